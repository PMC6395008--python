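"""Subgenome assignment of read-backed phased fragments.

The two subgenomes of a disomic allotetraploid are separated using sites
carrying a fixed allelic difference between the two parental panels
(diagnostic sites).  Each phased fragment (a haplotype block over an
accession's heterozygous sites) is oriented by majority vote over its
diagnostic sites; blocks with fewer than two informative sites are
unassignable and blocks whose prevailing orientation is supported by less
than 90% of informative sites are chimeric (switch errors) -- both are
replaced by missing data.  Homozygous sites are copied to both subgenome
sequences, and the same proportion of missing data introduced into
heterozygous sites is introduced into homozygous sites so the phased
alignment keeps the heterozygosity of the unphased input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, HaplotypeAlignment

PROV_NONE, PROV_BLOCK, PROV_HOMOZYGOUS, PROV_BALANCED = 0, 1, 2, 3


class PhasingError(ValueError):
    pass


@dataclass
class DiagnosticSiteSet:
    """Sites fixed-different between the two parental panels.

    ``co_allele``/``cg_allele`` are 0 (ref) or 1 (alt): the allele fixed in
    the selfing-parent (CO) and outcrossing-parent (CG) panel respectively.
    """

    scaffolds: np.ndarray
    positions: np.ndarray
    co_allele: np.ndarray
    cg_allele: np.ndarray

    def __post_init__(self) -> None:
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.co_allele = np.asarray(self.co_allele, dtype=np.int8)
        self.cg_allele = np.asarray(self.cg_allele, dtype=np.int8)
        if np.any(self.co_allele == self.cg_allele):
            raise PhasingError("diagnostic site with identical parental alleles")

    def __len__(self) -> int:
        return len(self.positions)

    def lookup(self) -> dict:
        """(scaffold, position) -> co_allele."""
        return {
            (s, int(p)): int(a)
            for s, p, a in zip(self.scaffolds, self.positions, self.co_allele)
        }


@dataclass
class PhasedFragment:
    """One haplotype block: phased alleles of haplotype A at ordered het sites."""

    accession: str
    scaffold: str
    positions: np.ndarray  # 1-based, strictly increasing
    states: np.ndarray  # allele on haplotype A at each site (0 ref / 1 alt)
    fv: np.ndarray  # per-site flagged-invalid ("FV") indicator

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int8)
        self.fv = np.asarray(self.fv, dtype=bool)
        if len(self.positions) == 0:
            raise PhasingError("empty fragment")
        if np.any(np.diff(self.positions) <= 0):
            raise PhasingError("fragment sites not strictly increasing")


@dataclass
class FragmentAssignment:
    n_informative: int
    consistency: float  # fraction of informative sites supporting the prevailing state
    orientation: str  # "co-first" (haplotype A is Co), "cg-first", or "unassigned"
    verdict: str  # "assigned", "chimeric", "unassignable"


@dataclass
class SubgenomeAlignment:
    """Per-accession Co and Cg sequences over the retained site table."""

    accessions: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    co: np.ndarray  # accessions x sites, 0/1/-1
    cg: np.ndarray
    provenance: np.ndarray  # accessions x sites, PROV_* codes
    stats: pd.DataFrame | None = None  # per-accession QC gathered during assembly

    def co_alignment(self) -> HaplotypeAlignment:
        return HaplotypeAlignment(
            [f"{a}_Co" for a in self.accessions],
            self.scaffolds, self.positions, self.ref, self.alt, self.co,
        )

    def cg_alignment(self) -> HaplotypeAlignment:
        return HaplotypeAlignment(
            [f"{a}_Cg" for a in self.accessions],
            self.scaffolds, self.positions, self.ref, self.alt, self.cg,
        )

    def heterozygosity(self) -> np.ndarray:
        """Per accession: het fraction among sites with both alleles present."""
        both = (self.co != MISSING) & (self.cg != MISSING)
        diff = (self.co != self.cg) & both
        with np.errstate(invalid="ignore"):
            return diff.sum(axis=1) / both.sum(axis=1)


# ---------------------------------------------------------------------------
# Fragment file format: one block per line, tab-separated
#   accession  scaffold  pos1,pos2,...  states(0/1 string)  fv(0/1 string)


def write_fragments(fragments: list[PhasedFragment], path: str) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f"{f.accession}\t{f.scaffold}\t"
                + ",".join(map(str, f.positions))
                + "\t" + "".join(map(str, f.states))
                + "\t" + "".join("1" if x else "0" for x in f.fv)
                + "\n"
            )


def read_fragments(path: str) -> list[PhasedFragment]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                acc, scaf, pos, states, fv = line.split("\t")
                out.append(
                    PhasedFragment(
                        accession=acc, scaffold=scaf,
                        positions=np.array([int(p) for p in pos.split(",")]),
                        states=np.array([int(c) for c in states], dtype=np.int8),
                        fv=np.array([c == "1" for c in fv]),
                    )
                )
            except Exception as e:  # noqa: BLE001
                raise PhasingError(f"malformed fragment line {ln}: {e}") from e
    return out


# ---------------------------------------------------------------------------
# Operations


def find_diagnostic_sites(
    panel_co: GenotypeMatrix,
    panel_cg: GenotypeMatrix,
    max_missing: float = 0.2,
    require_fixed_het: GenotypeMatrix | None = None,
    fixed_het_fraction: float = 1.0,
) -> DiagnosticSiteSet:
    """Sites fixed-different between the parental panels.

    A site qualifies iff within each panel the non-missing genotypes are
    monomorphic homozygous (a heterozygous parental genotype counts as
    polymorphism and excludes the site), the two panel alleles differ, and
    each panel's missing fraction is at most ``max_missing`` (inclusive).

    ``require_fixed_het`` optionally pre-restricts candidates to sites
    heterozygous in at least ``fixed_het_fraction`` of that matrix's
    non-missing genotypes (fixed heterozygotes in the tetraploid); off by
    default.
    """
    if panel_co.n_sites != panel_cg.n_sites or np.any(
        panel_co.positions != panel_cg.positions
    ):
        raise PhasingError("parental panels do not share a site index")

    def fixed_allele(m: GenotypeMatrix):
        """Per site: fixed hom allele (0/1) or -9 if polymorphic/het/no data."""
        called = m.gt != MISSING
        n_called = called.sum(axis=0)
        any_het = np.any(m.gt == HET, axis=0)
        n_ref = (m.gt == HOM_REF).sum(axis=0)
        n_alt = (m.gt == HOM_ALT).sum(axis=0)
        allele = np.full(m.n_sites, -9, dtype=np.int8)
        allele[(n_ref == n_called) & (n_called > 0)] = 0
        allele[(n_alt == n_called) & (n_called > 0)] = 1
        allele[any_het | (n_called == 0)] = -9
        return allele, 1 - n_called / m.n_samples

    a_co, miss_co = fixed_allele(panel_co)
    a_cg, miss_cg = fixed_allele(panel_cg)
    keep = (
        (a_co >= 0) & (a_cg >= 0) & (a_co != a_cg)
        & (miss_co <= max_missing) & (miss_cg <= max_missing)
    )
    if require_fixed_het is not None:
        called = require_fixed_het.gt != MISSING
        n_called = called.sum(axis=0)
        het_frac = np.where(
            n_called > 0, (require_fixed_het.gt == HET).sum(axis=0) / np.maximum(n_called, 1), 0
        )
        keep &= het_frac >= fixed_het_fraction
    idx = np.flatnonzero(keep)
    return DiagnosticSiteSet(
        panel_co.scaffolds[idx], panel_co.positions[idx], a_co[idx], a_cg[idx]
    )


def classify_fragment(
    fragment: PhasedFragment,
    diag: DiagnosticSiteSet | dict,
    min_informative: int = 2,
    min_consistency: float = 0.9,
) -> FragmentAssignment:
    """Orient a fragment by majority vote over its diagnostic sites.

    Informative sites are the fragment's non-FV sites that are diagnostic.
    The prevailing orientation is whichever subgenome haplotype A agrees
    with at the majority of informative sites; consistency is the majority
    fraction.  Verdicts: ``unassignable`` below ``min_informative``
    informative sites, ``chimeric`` below ``min_consistency`` (an even
    split has no prevailing state and is chimeric), else ``assigned``.
    """
    table = diag.lookup() if isinstance(diag, DiagnosticSiteSet) else diag
    votes_co = 0
    n_inf = 0
    for pos, state, fv in zip(fragment.positions, fragment.states, fragment.fv):
        if fv:
            continue
        co_allele = table.get((fragment.scaffold, int(pos)))
        if co_allele is None:
            continue
        n_inf += 1
        if state == co_allele:
            votes_co += 1
    if n_inf < min_informative:
        return FragmentAssignment(n_inf, float("nan") if n_inf == 0 else max(
            votes_co, n_inf - votes_co) / n_inf, "unassigned", "unassignable")
    c = max(votes_co, n_inf - votes_co) / n_inf
    if votes_co == n_inf - votes_co or c < min_consistency:
        return FragmentAssignment(n_inf, c, "unassigned", "chimeric")
    orientation = "co-first" if votes_co > n_inf - votes_co else "cg-first"
    return FragmentAssignment(n_inf, c, orientation, "assigned")


def assemble_subgenomes(
    fragments: list[PhasedFragment],
    unphased: GenotypeMatrix,
    diag: DiagnosticSiteSet,
    seed: int = 0,
    min_informative: int = 2,
    min_consistency: float = 0.9,
) -> SubgenomeAlignment:
    """Concatenate assigned fragments into per-accession Co/Cg sequences.

    Assigned fragments write their alleles per orientation; chimeric and
    unassignable fragment sites, FV-flagged sites, uncovered heterozygous
    sites, and sites where two assigned fragments disagree become missing
    on both haplotypes.  Homozygous sites are copied to both haplotypes.
    Per accession and scaffold, the fraction q of heterozygous sites that
    ended missing is matched by masking the same fraction of homozygous
    sites (sampled uniformly with ``seed``), so output heterozygosity
    equals input heterozygosity.
    """
    rng = np.random.default_rng(seed)
    n_acc, n_sites = unphased.gt.shape
    co = np.full((n_acc, n_sites), MISSING, dtype=np.int8)
    cg = np.full((n_acc, n_sites), MISSING, dtype=np.int8)
    prov = np.zeros((n_acc, n_sites), dtype=np.int8)

    col_of = {
        (s, int(p)): j for j, (s, p) in enumerate(zip(unphased.scaffolds, unphased.positions))
    }
    acc_of = {a: i for i, a in enumerate(unphased.samples)}
    table = diag.lookup()

    hom_ref = unphased.gt == HOM_REF
    hom_alt = unphased.gt == HOM_ALT
    co[hom_ref] = 0
    cg[hom_ref] = 0
    co[hom_alt] = 1
    cg[hom_alt] = 1
    prov[hom_ref | hom_alt] = PROV_HOMOZYGOUS

    conflict: set[tuple[int, int]] = set()
    verdict_counts = {a: {"assigned": 0, "chimeric": 0, "unassignable": 0} for a in unphased.samples}
    block_sites: dict[str, list[int]] = {a: [] for a in unphased.samples}
    block_spans: dict[str, list[int]] = {a: [] for a in unphased.samples}

    for frag in fragments:
        if frag.accession not in acc_of:
            raise PhasingError(f"fragment for unknown accession {frag.accession}")
        i = acc_of[frag.accession]
        cols = []
        for p in frag.positions:
            j = col_of.get((frag.scaffold, int(p)))
            if j is None:
                raise PhasingError(
                    f"fragment references unknown site {frag.scaffold}:{p}"
                )
            cols.append(j)
        asg = classify_fragment(frag, table, min_informative, min_consistency)
        verdict_counts[frag.accession][asg.verdict] += 1
        block_sites[frag.accession].append(len(frag.positions))
        block_spans[frag.accession].append(int(frag.positions[-1] - frag.positions[0] + 1))
        if asg.verdict != "assigned":
            continue  # sites stay missing
        for j, state, fv in zip(cols, frag.states, frag.fv):
            if fv:
                continue
            a_co = state if asg.orientation == "co-first" else 1 - state
            if (i, j) in conflict:
                continue
            if prov[i, j] == PROV_BLOCK and co[i, j] != a_co:
                co[i, j] = MISSING
                cg[i, j] = MISSING
                prov[i, j] = PROV_NONE
                conflict.add((i, j))
                continue
            co[i, j] = a_co
            cg[i, j] = 1 - a_co
            prov[i, j] = PROV_BLOCK

    # balanced missingness: mask homozygous sites at the same rate per scaffold
    het = unphased.gt == HET
    stats_rows = []
    for i, acc in enumerate(unphased.samples):
        q_num = q_den = 0
        for scaf in pd.unique(unphased.scaffolds):
            sel = unphased.scaffolds == scaf
            het_cols = np.flatnonzero(het[i] & sel)
            lost = het_cols[prov[i, het_cols] != PROV_BLOCK]
            q = len(lost) / len(het_cols) if len(het_cols) else 0.0
            q_num += len(lost)
            q_den += len(het_cols)
            if q > 0:
                hom_cols = np.flatnonzero((hom_ref[i] | hom_alt[i]) & sel)
                n_mask = int(round(q * len(hom_cols)))
                if n_mask:
                    masked = rng.choice(hom_cols, size=n_mask, replace=False)
                    co[i, masked] = MISSING
                    cg[i, masked] = MISSING
                    prov[i, masked] = PROV_BALANCED
        q_acc = q_num / q_den if q_den else 0.0
        ns = block_sites[acc]
        sp = block_spans[acc]
        stats_rows.append(
            dict(
                accession=acc,
                n_fragments=len(ns),
                assigned=verdict_counts[acc]["assigned"],
                chimeric=verdict_counts[acc]["chimeric"],
                unassignable=verdict_counts[acc]["unassignable"],
                block_sites_mean=float(np.mean(ns)) if ns else 0.0,
                block_span_mean=float(np.mean(sp)) if sp else 0.0,
                block_span_median=float(np.median(sp)) if sp else 0.0,
                q_missing=q_acc,
                n_het_input=int(q_den),
            )
        )
    stats = pd.DataFrame(stats_rows)

    aln = SubgenomeAlignment(
        accessions=list(unphased.samples),
        scaffolds=unphased.scaffolds, positions=unphased.positions,
        ref=unphased.ref, alt=unphased.alt,
        co=co, cg=cg, provenance=prov, stats=stats,
    )
    called = unphased.gt != MISSING
    with np.errstate(invalid="ignore"):
        het_in = het.sum(axis=1) / called.sum(axis=1)
    aln.stats["het_input"] = het_in
    aln.stats["het_output"] = aln.heterozygosity()
    return aln


def phasing_report(aln: SubgenomeAlignment) -> pd.DataFrame:
    """Per-accession QC table: block lengths, verdict counts, q, het before/after."""
    if aln.stats is None:
        raise PhasingError("alignment carries no assembly statistics")
    return aln.stats.copy()


def write_phased_vcf(aln: SubgenomeAlignment, path: str) -> None:
    """Emit the phased alignment as a VCF with _Co/_Cg haploid pseudo-samples."""
    names = [f"{a}_Co" for a in aln.accessions] + [f"{a}_Cg" for a in aln.accessions]
    haps = np.vstack([aln.co, aln.cg])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf in pd.unique(aln.scaffolds):
            ln = int(aln.positions[aln.scaffolds == scaf].max()) + 1000
            fh.write(f"##contig=<ID={scaf},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n"
        )
        for j in range(len(aln.positions)):
            cells = ["." if haps[i, j] == MISSING else str(int(haps[i, j])) for i in range(len(names))]
            fh.write(
                f"{aln.scaffolds[j]}\t{aln.positions[j]}\t.\t{aln.ref[j]}\t{aln.alt[j]}"
                "\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )
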