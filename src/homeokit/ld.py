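"""Linkage-disequilibrium r-squared and decay profiles for phasing validation.

If subgenomes have been separated correctly, r-squared between pairs of
SNPs from the same subgenome decays with distance (selfing keeps LD high
and decay gradual), whereas pairs that straddle the two subgenomes -- or a
random mixture of SNPs from both -- show no decay.  Profiles pair seeded
"principal" SNPs with the following SNPs of a chosen source and aggregate
mean r-squared into SNP-offset bins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .variants import MISSING, HaplotypeAlignment

MIN_COMPLETE = 5  # SNP pairs with fewer complete samples are skipped


def r_squared(x: np.ndarray, y: np.ndarray, min_complete: int = MIN_COMPLETE) -> float:
    """Squared Pearson correlation of allele codes over pairwise-complete samples.

    Returns nan when fewer than ``min_complete`` samples carry both SNPs
    or either SNP is monomorphic among them.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < min_complete:
        return float("nan")
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _r2_one_vs_many(x: np.ndarray, Y: np.ndarray, min_complete: int) -> np.ndarray:
    """Vectorized r-squared of one SNP against the columns of Y (samples x k)."""
    ok = (x[:, None] != MISSING) & (Y != MISSING)
    n = ok.sum(axis=0).astype(float)
    xf = np.where(x == MISSING, 0, x).astype(float)[:, None]
    yf = np.where(Y == MISSING, 0, Y).astype(float)
    sx = (xf * ok).sum(axis=0)
    sy = (yf * ok).sum(axis=0)
    sxx = (xf * xf * ok).sum(axis=0)
    syy = (yf * yf * ok).sum(axis=0)
    sxy = (xf * yf * ok).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[(n < min_complete) | (vx <= 0) | (vy <= 0)] = np.nan
    return r2


def ld_decay_profile(
    co: HaplotypeAlignment,
    cg: HaplotypeAlignment,
    comparison: str = "within-co",
    n_principal: int = 1000,
    n_next: int = 1000,
    n_bins: int = 100,
    seed: int = 0,
    min_complete: int = MIN_COMPLETE,
) -> pd.DataFrame:
    """Mean r-squared by SNP-offset bin for one comparison scheme.

    Schemes: ``within-co`` / ``within-cg`` pair principal SNPs with the
    next SNPs of the same subgenome; ``between`` pairs principal SNPs of
    one subgenome with the following SNPs of the other; ``random-mix``
    samples principals and partners from a positional merge of both
    subgenomes' SNPs.  Per scaffold, ``n_principal`` principal SNPs are
    sampled (seeded) and each is paired with the next ``n_next`` SNPs
    downstream; offsets are aggregated into ``n_bins`` equal bins.
    """
    rng = np.random.default_rng(seed)
    bin_width = max(1, n_next // n_bins)

    def columns_for(scheme):
        # returns (principal source, partner source) as (haps, positions) per scaffold
        if scheme == "within-co":
            return (co, co)
        if scheme == "within-cg":
            return (cg, cg)
        if scheme == "between":
            return (co, cg)
        if scheme == "random-mix":
            return None
        raise ValueError(f"unknown comparison {scheme!r}")

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    scaffolds = pd.unique(np.concatenate([co.scaffolds, cg.scaffolds]))
    for scaf in scaffolds:
        if comparison == "random-mix":
            sel_co = np.flatnonzero(co.scaffolds == scaf)
            sel_cg = np.flatnonzero(cg.scaffolds == scaf)
            pos = np.concatenate([co.positions[sel_co], cg.positions[sel_cg]])
            order = np.argsort(pos, kind="stable")
            H = np.hstack([co.haps[:, sel_co], cg.haps[:, sel_cg]])[:, order]
            Hp, pos_p, pos_q = H, pos[order], pos[order]
        else:
            src_p, src_q = columns_for(comparison)
            sel_p = np.flatnonzero(src_p.scaffolds == scaf)
            sel_q = np.flatnonzero(src_q.scaffolds == scaf)
            H = src_p.haps[:, sel_p]
            Hp = src_q.haps[:, sel_q]
            pos_p = src_p.positions[sel_p]
            pos_q = src_q.positions[sel_q]
        if H.shape[1] < 2:
            continue
        n_snps = H.shape[1]
        if n_snps < n_next + 1:
            warnings.warn(f"{scaf}: only {n_snps} SNPs; fewer pairs than requested")
        k = min(n_principal, n_snps)
        principals = np.sort(rng.choice(n_snps, size=k, replace=False))
        for p in principals:
            if comparison == "between":
                start = int(np.searchsorted(pos_q, pos_p[p], side="right"))
            elif comparison == "random-mix":
                start = p + 1
            else:
                start = p + 1
            stop = min(start + n_next, Hp.shape[1])
            if stop <= start:
                continue
            r2 = _r2_one_vs_many(H[:, p], Hp[:, start:stop], min_complete)
            offs = np.arange(stop - start)  # offset 0 == first following SNP
            bins = np.minimum(offs // bin_width, n_bins - 1)
            ok = ~np.isnan(r2)
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "comparison": comparison,
            "bin": np.arange(n_bins),
            "offset_snps": (np.arange(n_bins) + 0.5) * bin_width,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def shuffle_phase_labels(
    co: HaplotypeAlignment, cg: HaplotypeAlignment, seed: int = 0
) -> tuple[HaplotypeAlignment, HaplotypeAlignment]:
    """Negative control: randomly swap the two subgenome labels per accession-site.

    Both alignments must share accession order.  Sites where the two
    subgenomes differ have their alleles exchanged with probability 1/2
    independently per accession, destroying within-subgenome LD structure
    while keeping site-wise allele content identical.
    """
    rng = np.random.default_rng(seed)
    assert co.haps.shape[0] == cg.haps.shape[0]
    # operate on the positional union by swapping within each subgenome's own sites
    co2, cg2 = co.haps.copy(), cg.haps.copy()
    swap_co = rng.random(co2.shape) < 0.5
    swap_cg = rng.random(cg2.shape) < 0.5
    # swapping a Co-private SNP moves its alt allele onto the Cg haplotype, which at
    # that site is ref: model label shuffling as exchanging alleles at swapped cells
    co_new = np.where(swap_co, 0, co2)
    cg_at_co = np.where(swap_co, co2, 0)
    cg_new = np.where(swap_cg, 0, cg2)
    co_at_cg = np.where(swap_cg, cg2, 0)
    co_a = HaplotypeAlignment(co.names, co.scaffolds, co.positions, co.ref, co.alt, co_new)
    cg_b = HaplotypeAlignment(cg.names, cg.scaffolds, cg.positions, cg.ref, cg.alt, cg_new)
    # the displaced alleles join the opposite subgenome's site list
    co_extra = HaplotypeAlignment(co.names, cg.scaffolds, cg.positions, cg.ref, cg.alt, co_at_cg)
    cg_extra = HaplotypeAlignment(cg.names, co.scaffolds, co.positions, co.ref, co.alt, cg_at_co)
    co_merged = _merge(co_a, co_extra)
    cg_merged = _merge(cg_b, cg_extra)
    return co_merged, cg_merged


def _merge(a: HaplotypeAlignment, b: HaplotypeAlignment) -> HaplotypeAlignment:
    scaf = np.concatenate([a.scaffolds, b.scaffolds])
    pos = np.concatenate([a.positions, b.positions])
    ref = np.concatenate([a.ref, b.ref])
    alt = np.concatenate([a.alt, b.alt])
    haps = np.hstack([a.haps, b.haps])
    order = np.lexsort((pos, scaf.astype(str)))
    return HaplotypeAlignment(a.names, scaf[order], pos[order], ref[order], alt[order], haps[:, order])
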