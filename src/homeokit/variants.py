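"""Genotype matrices: VCF I/O, depth/missingness filters, masks, pseudo-phasing.

Genotypes are stored as small integer codes over biallelic SNPs only:
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.  Haplotypes use
``0`` ref allele, ``1`` alt allele, ``-1`` missing.  Positions are 1-based
(VCF convention) in site tables; interval masks are 0-based half-open
(BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MISSING = -1

HOM_REF, HET, HOM_ALT = 0, 1, 2


class VariantError(ValueError):
    """Raised for malformed or inconsistent variant inputs."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with optional per-genotype depth.

    ``gt`` has shape ``(n_samples, n_sites)`` with codes 0/1/2/-1.
    Sites are sorted by (scaffold, position); positions are 1-based.
    """

    samples: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    depth: np.ndarray | None = None
    skipped_records: int = 0

    def __post_init__(self) -> None:
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), len(self.positions)):
            raise VariantError(
                f"gt shape {self.gt.shape} != (n_samples, n_sites) "
                f"({len(self.samples)}, {len(self.positions)})"
            )
        for scaf in pd.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            if np.any(np.diff(pos) <= 0):
                raise VariantError(f"positions not strictly increasing on {scaf}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            scaffolds=self.scaffolds[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        missing = [n for n in names if n not in self.samples]
        if missing:
            raise VariantError(f"samples not present: {missing}")
        rows = [self.samples.index(n) for n in names]
        return replace(
            self,
            samples=list(names),
            gt=self.gt[rows],
            depth=None if self.depth is None else self.depth[rows],
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return np.mean(self.gt == MISSING, axis=0)

    def site_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.scaffolds, self.positions])


@dataclass
class HaplotypeAlignment:
    """Haploid allele matrix (0 ref / 1 alt / -1 missing) over a site table."""

    names: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haps: np.ndarray

    def __post_init__(self) -> None:
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haps = np.asarray(self.haps, dtype=np.int8)

    @property
    def n_haps(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def take_sites(self, idx: np.ndarray) -> "HaplotypeAlignment":
        idx = np.asarray(idx)
        return HaplotypeAlignment(
            self.names,
            self.scaffolds[idx],
            self.positions[idx],
            self.ref[idx],
            self.alt[idx],
            self.haps[:, idx],
        )

    def subset(self, names: list[str]) -> "HaplotypeAlignment":
        rows = [self.names.index(n) for n in names]
        return HaplotypeAlignment(
            list(names), self.scaffolds, self.positions, self.ref, self.alt, self.haps[rows]
        )

    def to_fasta(self, path: str) -> None:
        """Write haplotypes as sequences of ref/alt bases ('N' for missing)."""
        with open(path, "w") as fh:
            for i, name in enumerate(self.names):
                alleles = np.where(
                    self.haps[i] == 0, self.ref, np.where(self.haps[i] == 1, self.alt, "N")
                )
                fh.write(f">{name}\n{''.join(alleles)}\n")


@dataclass
class SiteMask:
    """Sorted, merged 0-based half-open intervals keyed by scaffold."""

    intervals: pd.DataFrame  # columns: scaffold, start, end
    label: str = "custom"

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        merged = []
        for scaf, grp in df.groupby("scaffold", sort=True):
            grp = grp.sort_values("start")
            cur_s, cur_e = None, None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((scaf, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                merged.append((scaf, cur_s, cur_e))
        self.intervals = pd.DataFrame(merged, columns=["scaffold", "start", "end"])

    @classmethod
    def from_bed(cls, path: str, label: str = "custom") -> "SiteMask":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["scaffold", "start", "end"],
            comment="#",
        )
        return cls(df, label=label)

    def contains(self, scaffolds: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """True where 1-based position falls in a masked interval."""
        out = np.zeros(len(positions), dtype=bool)
        zero_based = np.asarray(positions) - 1
        for scaf, grp in self.intervals.groupby("scaffold"):
            sel = scaffolds == scaf
            if not np.any(sel):
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            # merged & sorted: position is inside iff the preceding start's end exceeds it
            k = np.searchsorted(starts, zero_based[sel], side="right") - 1
            hit = (k >= 0) & (zero_based[sel] < ends[np.clip(k, 0, None)])
            out[np.flatnonzero(sel)[hit]] = True
        return out


# ---------------------------------------------------------------------------
# VCF I/O


def read_genotypes(vcf_path: str, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are skipped and counted in
    ``skipped_records``.  Depth is taken from FORMAT/DP when present.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=True)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in vcf.samples]
        if absent:
            raise VariantError(f"samples not in VCF: {absent}")
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)

    scafs, pos, ref, alt, gts, dps = [], [], [], [], [], []
    skipped = 0
    has_depth = False
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        scafs.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        g = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        gts.append(g)
        try:
            dp = rec.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            has_depth = True
            dps.append(dp[:, 0].astype(np.int32))
        else:
            dps.append(np.full(len(samples), -1, dtype=np.int32))
    gt = np.array(gts, dtype=np.int8).T if gts else np.zeros((len(samples), 0), np.int8)
    depth = np.array(dps, dtype=np.int32).T if (dps and has_depth) else None
    m = GenotypeMatrix(
        samples=samples,
        scaffolds=np.array(scafs, dtype=object),
        positions=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        gt=gt,
        depth=depth,
    )
    m.skipped_records = skipped
    return m


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(m: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as an uncompressed diploid VCF (GT[:DP])."""
    fmt = "GT" if m.depth is None else "GT:DP"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if m.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for scaf in pd.unique(m.scaffolds):
            ln = int(m.positions[m.scaffolds == scaf].max()) + 1000
            fh.write(f"##contig=<ID={scaf},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples) + "\n"
        )
        for j in range(m.n_sites):
            cells = []
            for i in range(m.n_samples):
                c = _GT_STR[int(m.gt[i, j])]
                if m.depth is not None:
                    c += f":{int(m.depth[i, j])}"
                cells.append(c)
            fh.write(
                f"{m.scaffolds[j]}\t{m.positions[j]}\t.\t{m.ref[j]}\t{m.alt[j]}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filters


def filter_genotypes(
    m: GenotypeMatrix, min_depth: int = 6, max_depth: int = 100
) -> GenotypeMatrix:
    """Set genotypes with depth outside [min_depth, max_depth] to missing.

    Boundaries are inclusive: depths of exactly ``min_depth`` or
    ``max_depth`` are kept.  Pass-through (with a warning) when the matrix
    carries no depth information.
    """
    if m.depth is None:
        warnings.warn("no depth information; depth filter skipped")
        return m
    bad = (m.depth < min_depth) | (m.depth > max_depth)
    gt = m.gt.copy()
    gt[bad] = MISSING
    return replace(m, gt=gt)


def filter_missingness(m: GenotypeMatrix, max_missing: float = 0.8) -> GenotypeMatrix:
    """Drop sites whose missing-genotype fraction strictly exceeds ``max_missing``."""
    keep = m.missing_fraction() <= max_missing
    return m.take_sites(np.flatnonzero(keep))


def apply_mask(m: GenotypeMatrix, mask: SiteMask) -> GenotypeMatrix:
    """Drop sites falling inside masked intervals (0-based half-open)."""
    unknown = set(mask.intervals["scaffold"]) - set(pd.unique(m.scaffolds))
    if unknown:
        warnings.warn(f"mask scaffolds absent from matrix ignored: {sorted(unknown)}")
    inside = mask.contains(m.scaffolds, m.positions)
    return m.take_sites(np.flatnonzero(~inside))


def apply_info_filters(
    site_info: pd.DataFrame, thresholds: dict[str, tuple[str, float]]
) -> np.ndarray:
    """Generic per-site INFO threshold engine.

    ``thresholds`` maps field name to (op, cutoff) with op in {"<", ">"};
    a site fails if the field exists and the comparison holds (the caller
    drops failing sites).  Fields absent from ``site_info`` are ignored.
    Returns a boolean keep-array.
    """
    keep = np.ones(len(site_info), dtype=bool)
    for fieldname, (op, cut) in thresholds.items():
        if fieldname not in site_info.columns:
            continue
        vals = site_info[fieldname].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fail = (vals < cut) if op == "<" else (vals > cut)
        keep &= ~np.nan_to_num(fail, nan=False).astype(bool)
    return keep


GATK_DEFAULT_FILTERS = {
    "MQ": ("<", 30.0),
    "SOR": (">", 4.0),
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQRankSum": ("<", -20.0),
    "ReadPosRankSum_low": ("<", -10.0),
    "ReadPosRankSum_high": (">", 10.0),
}


# ---------------------------------------------------------------------------
# Pseudo-phasing


def pseudo_phase(m: GenotypeMatrix, seed: int) -> HaplotypeAlignment:
    """Split diploid genotypes into two haplotypes, randomizing het alleles.

    Homozygous genotypes are copied to both haplotypes; at heterozygous
    sites ref/alt are assigned to the two haplotypes by a fair coin per
    site; missing genotypes stay missing on both.  Allele frequencies are
    preserved exactly.
    """
    rng = np.random.default_rng(seed)
    n, s = m.gt.shape
    hap_a = np.full((n, s), MISSING, dtype=np.int8)
    hap_b = np.full((n, s), MISSING, dtype=np.int8)
    hap_a[m.gt == HOM_REF] = 0
    hap_b[m.gt == HOM_REF] = 0
    hap_a[m.gt == HOM_ALT] = 1
    hap_b[m.gt == HOM_ALT] = 1
    het = m.gt == HET
    coin = rng.integers(0, 2, size=(n, s)).astype(np.int8)
    hap_a[het] = coin[het]
    hap_b[het] = 1 - coin[het]
    names = [f"{s_}_hapA" for s_ in m.samples] + [f"{s_}_hapB" for s_ in m.samples]
    return HaplotypeAlignment(
        names, m.scaffolds, m.positions, m.ref, m.alt, np.vstack([hap_a, hap_b])
    )
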