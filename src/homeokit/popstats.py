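"""Sliding-window nucleotide diversity and divergence; codon degeneracy classes.

Per-site diversity uses the unbiased pairwise estimator
``2 p (1 - p) * n / (n - 1)`` computed with pairwise-complete haplotypes;
divergence (Dxy) is the mean per-accessible-site difference fraction over
all between-group haplotype pairs.  Windows are non-overlapping tiles
(default 100 kb).  When only SNPs are supplied the denominator is the
callable SNP count and values are flagged per-SNP ("unscaled"); passing
per-window accessible-site counts yields per-site values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, HaplotypeAlignment


class PopstatsError(ValueError):
    pass


@dataclass
class WindowStat:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    n_accessible: int
    value: float  # per-site; nan when no accessible sites


def tile_windows(scaffolds: np.ndarray, positions: np.ndarray, window_bp: int):
    """Non-overlapping [start, end) tiles covering each scaffold's sites."""
    out = []
    for scaf in pd.unique(scaffolds):
        pos = positions[scaffolds == scaf]
        last = int(pos.max())
        for start in range(0, last + 1, window_bp):
            out.append((str(scaf), start, start + window_bp))
    return out


def _site_pi(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site unbiased pi and a 'callable' flag (>= 2 non-missing haplotypes)."""
    called = haps != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, haps, 0).sum(axis=0)
    callable_ = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(callable_, alt / np.maximum(n, 1), 0.0)
        pi = np.where(callable_, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1), 0.0)
    return pi, callable_


def window_pi(
    aln: HaplotypeAlignment,
    window_bp: int = 100_000,
    accessible: dict | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per non-overlapping window.

    ``accessible`` optionally maps (scaffold, start) -> callable site count
    (variant plus invariant) for per-site scaling; otherwise the callable
    SNP count is used and the result carries ``unscaled=True``.
    """
    if aln.n_haps < 2:
        raise PopstatsError("pi requires at least 2 haplotypes")
    pi, callable_ = _site_pi(aln.haps)
    return _windowize(aln, pi, callable_, window_bp, accessible, "pi")


def window_dxy(
    aln_a: HaplotypeAlignment,
    aln_b: HaplotypeAlignment,
    window_bp: int = 100_000,
    accessible: dict | None = None,
) -> pd.DataFrame:
    """Absolute divergence per window: mean A-vs-B pairwise difference fraction."""
    if aln_a.n_haps < 1 or aln_b.n_haps < 1:
        raise PopstatsError("dxy requires at least 1 haplotype per group")
    if aln_a.n_sites != aln_b.n_sites:
        raise PopstatsError("alignments do not share a site table")
    a, b = aln_a.haps, aln_b.haps
    ca, cb = a != MISSING, b != MISSING
    # per-site mean difference over complete A x B pairs
    na, nb = ca.sum(0), cb.sum(0)
    alt_a, alt_b = np.where(ca, a, 0).sum(0), np.where(cb, b, 0).sum(0)
    n_pairs = na * nb
    callable_ = n_pairs >= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = alt_a * (nb - alt_b) + (na - alt_a) * alt_b
        dxy = np.where(callable_, diff / np.maximum(n_pairs, 1), 0.0)
    return _windowize(aln_a, dxy, callable_, window_bp, accessible, "dxy")


def _windowize(aln, site_vals, callable_, window_bp, accessible, name):
    rows = []
    unscaled = accessible is None
    if unscaled:
        warnings.warn(f"{name}: no accessible-site counts supplied; values are per callable SNP")
    for scaf, start, end in tile_windows(aln.scaffolds, aln.positions, window_bp):
        sel = (aln.scaffolds == scaf) & (aln.positions - 1 >= start) & (aln.positions - 1 < end)
        n_callable = int(callable_[sel].sum())
        denom = accessible.get((scaf, start), 0) if accessible else n_callable
        total = float(site_vals[sel][callable_[sel]].sum())
        value = total / denom if denom > 0 else np.nan
        rows.append(dict(scaffold=scaf, start=start, end=end, n_accessible=denom, value=value))
    df = pd.DataFrame(rows)
    df.attrs["statistic"] = name
    df.attrs["unscaled"] = unscaled
    return df


def bootstrap_compare(
    stats_a, stats_b, n_boot: int = 10_000, seed: int = 0
) -> float:
    """Two-sided bootstrap p-value for a difference in window means.

    Windows are resampled with replacement within each group; the p-value
    uses the add-one correction (k + 1) / (n_boot + 1), so the smallest
    attainable value is 2 / (n_boot + 1).
    """
    a = np.asarray(stats_a["value"] if isinstance(stats_a, pd.DataFrame) else stats_a, float)
    b = np.asarray(stats_b["value"] if isinstance(stats_b, pd.DataFrame) else stats_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise PopstatsError("bootstrap requires >= 2 windows per group")
    rng = np.random.default_rng(seed)
    ma = a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
    mb = b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
    diff = ma - mb
    p_le = (np.sum(diff <= 0) + 1) / (n_boot + 1)
    p_ge = (np.sum(diff >= 0) + 1) / (n_boot + 1)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Codon degeneracy


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _codon_degeneracy(codon: str, pos: int, table) -> str:
    """'0-fold' if every substitution at pos changes the amino acid, '4-fold' if none."""
    codon = codon.upper()
    if any(b not in "ACGT" for b in codon):
        return "other"
    aa = table.forward_table.get(codon, "*")
    changes = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if table.forward_table.get(alt, "*") != aa:
            changes += 1
    if changes == 3:
        return "0-fold"
    if changes == 0:
        return "4-fold"
    return "other"


def classify_degeneracy(ref_fasta: str, gff: str) -> pd.DataFrame:
    """Degeneracy class of every CDS position from a reference and gene models.

    Reverse-strand codons are read on the complement; positions covered by
    overlapping CDS with conflicting classes become "other"; a trailing
    partial codon is skipped with a warning.  Returns a DataFrame with
    columns ``scaffold, position (1-based), fold`` where fold is one of
    {"0-fold", "4-fold", "other"}.
    """
    import gffutils
    from Bio.Data import CodonTable
    from pyfaidx import Fasta

    table = CodonTable.unambiguous_dna_by_id[1]
    fasta = Fasta(ref_fasta)
    db = gffutils.create_db(
        gff, ":memory:", merge_strategy="create_unique", keep_order=True
    )

    classes: dict[tuple[str, int], str] = {}
    for cds in db.features_of_type("CDS"):
        scaf = cds.seqid
        seq = str(fasta[scaf][cds.start - 1 : cds.end])
        strand = cds.strand
        phase = int(cds.frame) if cds.frame not in (".", None) else 0
        if strand == "-":
            seq = seq[::-1].translate(_COMPLEMENT)
        seq = seq[phase:]
        if len(seq) % 3:
            warnings.warn(f"CDS {cds.id} length not divisible by 3; trailing codon skipped")
        n_codons = len(seq) // 3
        for c in range(n_codons):
            codon = seq[3 * c : 3 * c + 3]
            for off in range(3):
                fold = _codon_degeneracy(codon, off, table)
                # map back to genomic 1-based position
                i = phase + 3 * c + off  # index along coding direction
                if strand == "+":
                    gpos = cds.start + i
                else:
                    gpos = cds.end - i
                key = (scaf, gpos)
                if key in classes and classes[key] != fold:
                    classes[key] = "other"
                else:
                    classes[key] = fold
    rows = [(s, p, f) for (s, p), f in sorted(classes.items())]
    return pd.DataFrame(rows, columns=["scaffold", "position", "fold"])


def pi0_pi4(
    aln: HaplotypeAlignment, classmap: pd.DataFrame
) -> tuple[float, float, float]:
    """Diversity at 0-fold and 4-fold degenerate sites and their ratio.

    Sites of each class absent from the alignment contribute zero
    polymorphism but count in the denominator (they are monomorphic).  The
    ratio is nan (flagged undefined) when pi4 is 0 or a class is empty.
    """
    if aln.n_haps < 2:
        raise PopstatsError("pi requires at least 2 haplotypes")
    pi, callable_ = _site_pi(aln.haps)
    keys = pd.MultiIndex.from_arrays([aln.scaffolds, aln.positions])
    out = {}
    for fold in ("0-fold", "4-fold"):
        sub = classmap[classmap["fold"] == fold]
        n_class = len(sub)
        if n_class == 0:
            out[fold] = np.nan
            continue
        class_keys = pd.MultiIndex.from_frame(sub[["scaffold", "position"]])
        in_class = keys.isin(class_keys)
        out[fold] = float(pi[in_class & callable_].sum() / n_class)
    p0, p4 = out["0-fold"], out["4-fold"]
    ratio = p0 / p4 if (p4 and not np.isnan(p4) and p4 > 0 and not np.isnan(p0)) else np.nan
    return p0, p4, ratio


def select_least_missing(aln: HaplotypeAlignment, max_samples: int) -> HaplotypeAlignment:
    """Keep the ``max_samples`` haplotypes with the least missing data."""
    miss = np.mean(aln.haps == MISSING, axis=1)
    order = np.argsort(miss, kind="stable")[:max_samples]
    return aln.subset([aln.names[i] for i in sorted(order)])
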