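"""Synthetic allotetraploid data with known truth.

Emulates the data structure of a two-subgenome allotetraploid resequencing
study: a high-diversity outcrossing parental panel and a low-diversity
selfing parental panel separated by ~1-3% divergence, three diverged
tetraploid populations with disomic inheritance (one haplotype per
subgenome, near-zero within-subgenome heterozygosity), optional admixture
tracts copied from a diploid donor into one subgenome, read-backed
phased-fragment files with chimeras/flagged sites/coverage gaps, and
beta-binomially overdispersed DNA/RNA allele-count tables for
homeolog-specific expression.

The default mutation model is infinite-sites Bernoulli "sprinkling" over a
uniform genome split into named scaffolds: dependency-free, exact truth,
and no linkage.  A coalescent backend (msprime) is provided behind the
same containers for analyses that need linkage disequilibrium or genuine
genealogies (LD-decay validation, ABBA-BABA calibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix, HaplotypeAlignment

POPULATIONS = ("ASI", "EUR", "ME")

_BASES = np.array(list("ACGT"))


class SimParamError(ValueError):
    """Invalid simulation parameter."""


@dataclass
class SimParams:
    """Knobs of the synthetic generator.

    Rates are per site; lengths in bp.  Defaults mirror the emulated study
    design: 10 selfing-parent (CO) and 13 outcrossing-parent (CG) panel
    samples, ~31 tetraploid accessions in three populations, 2%
    inter-subgenome divergence, a ten-fold diversity asymmetry between the
    parental panels, and an 8-scaffold genome.
    """

    n_co_samples: int = 10
    n_cg_samples: int = 13
    n_accessions_per_pop: int = 10
    seq_length: int = 1_000_000
    n_scaffolds: int = 8
    inter_subgenome_divergence: float = 0.02
    theta_cg: float = 0.01
    theta_co: float = 0.001
    outgroup_divergence: float = 0.03
    pop_divergence: float = 0.003
    accession_theta: float = 0.0002
    admixture_tracts: list = field(default_factory=list)  # (population, subgenome, donor, fraction)
    tract_length_mean: float = 100_000.0
    fragment_length_mean: float = 20_000.0
    gap_length_mean: float = 4_000.0
    chimera_rate: float = 0.05
    fv_rate: float = 0.02
    missing_rate: float = 0.05
    depth_mean: float = 30.0
    # HSE count-table knobs
    n_genes: int = 200
    gene_length: int = 2_000
    max_snps_per_gene: int = 4
    dna_depth: float = 100.0
    rna_depth: float = 100.0
    hse_fraction: float = 0.2
    hse_effect: tuple = (0.3, 0.7)
    rho_dna: float = 0.005
    rho_rna: float = 0.005
    biased_snp_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length <= 0:
            raise SimParamError("seq_length must be positive")
        props = dict(
            inter_subgenome_divergence=self.inter_subgenome_divergence,
            theta_cg=self.theta_cg,
            theta_co=self.theta_co,
            outgroup_divergence=self.outgroup_divergence,
            pop_divergence=self.pop_divergence,
            accession_theta=self.accession_theta,
            chimera_rate=self.chimera_rate,
            fv_rate=self.fv_rate,
            missing_rate=self.missing_rate,
            hse_fraction=self.hse_fraction,
            biased_snp_fraction=self.biased_snp_fraction,
        )
        for k, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise SimParamError(f"{k}={v} outside [0, 1]")
        for _, _, _, frac in self.admixture_tracts:
            if not 0.0 <= frac <= 1.0:
                raise SimParamError(f"admixture tract fraction {frac} outside [0, 1]")

    def scaffold_length(self) -> int:
        return self.seq_length // self.n_scaffolds

    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    accessions: list[str]
    populations: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray  # 1-based within scaffold
    pos_global: np.ndarray  # 0-based over the whole genome
    ref: np.ndarray
    alt: np.ndarray
    co_haps: np.ndarray  # accessions x sites, 0/1
    cg_haps: np.ndarray
    tracts: pd.DataFrame  # accession, subgenome, donor, start, end (0-based half-open, global bp)
    fragment_truth: pd.DataFrame | None = None
    hse_genes: pd.DataFrame | None = None
    biased_snps: np.ndarray | None = None

    def inter_hap_het(self) -> np.ndarray:
        """Per-accession fraction of sites where the two subgenome alleles differ."""
        return np.mean(self.co_haps != self.cg_haps, axis=1)

    def co_alignment(self) -> HaplotypeAlignment:
        return HaplotypeAlignment(
            [f"{a}_Co" for a in self.accessions],
            self.scaffolds, self.positions, self.ref, self.alt, self.co_haps,
        )

    def cg_alignment(self) -> HaplotypeAlignment:
        return HaplotypeAlignment(
            [f"{a}_Cg" for a in self.accessions],
            self.scaffolds, self.positions, self.ref, self.alt, self.cg_haps,
        )

    def tracts_to_bed(self, path: str) -> None:
        rows = []
        for _, t in self.tracts.iterrows():
            rows.append(
                f"{t.scaffold}\t{t.local_start}\t{t.local_end}\t"
                f"{t.accession}:{t.subgenome}:{t.donor}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + ("\n" if rows else ""))


@dataclass
class ParentalPanels:
    """Output of :func:`simulate_parental_panels` plus internal state reused downstream."""

    params: SimParams
    scaffolds: np.ndarray
    positions: np.ndarray
    pos_global: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    co_panel: GenotypeMatrix
    cg_panel: GenotypeMatrix
    outgroup: HaplotypeAlignment
    co_panel_haps: np.ndarray  # haplotype truth (n_co x S)
    cg_panel_haps: np.ndarray  # (2*n_cg x S)
    site_class: np.ndarray  # {"div", "cg", "co", "og"}
    _pos_pool: np.ndarray = field(repr=False, default=None)
    _pool_cursor: int = 0


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _global_to_scaffold(pos_global: np.ndarray, params: SimParams):
    ls = params.scaffold_length()
    idx = np.minimum(pos_global // ls, params.n_scaffolds - 1)
    names = np.array(params.scaffold_names(), dtype=object)
    local = pos_global - idx * ls + 1  # 1-based
    return names[idx], local


def _sfs_counts(rng, n_hap: int, n_sites: int) -> np.ndarray:
    """Derived-allele counts drawn from the standard neutral frequency spectrum."""
    i = np.arange(1, n_hap)
    w = 1.0 / i
    return rng.choice(i, size=n_sites, p=w / w.sum())


def _assign_derived(rng, n_hap: int, counts: np.ndarray) -> np.ndarray:
    """Haplotype x site 0/1 matrix with the given derived-allele counts."""
    m = np.zeros((n_hap, len(counts)), dtype=np.int8)
    for j, c in enumerate(counts):
        m[rng.choice(n_hap, size=c, replace=False), j] = 1
    return m


def _random_ref_alt(rng, n: int):
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i].astype(object), _BASES[alt_i].astype(object)


def _apply_missing_and_depth(rng, gt: np.ndarray, params: SimParams):
    depth = rng.poisson(params.depth_mean, size=gt.shape).astype(np.int32)
    gt = gt.copy()
    if params.missing_rate > 0:
        miss = rng.random(gt.shape) < params.missing_rate
        gt[miss] = MISSING
    return gt, depth


def simulate_parental_panels(params: SimParams) -> ParentalPanels:
    """Draw the two parental panels, the outgroup, and the truth haplotypes.

    Two ancestral sequences separated by ``inter_subgenome_divergence`` are
    decorated with within-panel polymorphism calibrated so the expected
    per-site diversity equals ``theta_cg`` / ``theta_co``.  The selfing CO
    panel is emitted fully homozygous (one haplotype per sample); the
    outcrossing CG panel carries Hardy-Weinberg heterozygosity (two
    haplotypes per sample).  The outgroup is more divergent from both
    panels than they are from each other.
    """
    ss = np.random.SeedSequence(params.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_pos, r_div, r_cg, r_co, r_og, r_emit = rngs

    L = params.seq_length
    pos_pool = r_pos.permutation(L)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        if cursor + n > len(pos_pool):
            raise SimParamError("genome too short for requested site density")
        out = pos_pool[cursor : cursor + n]
        cursor += n
        return out

    n_hap_cg = 2 * params.n_cg_samples
    n_hap_co = params.n_co_samples

    n_div = r_div.binomial(L, params.inter_subgenome_divergence)
    n_cg = int(round(params.theta_cg * L * _harmonic(n_hap_cg))) if n_hap_cg > 1 else 0
    n_co = int(round(params.theta_co * L * _harmonic(n_hap_co))) if n_hap_co > 1 else 0
    n_og = r_og.binomial(L, params.outgroup_divergence)

    g_div, g_cg, g_co, g_og = take(n_div), take(n_cg), take(n_co), take(n_og)
    pos_global = np.concatenate([g_div, g_cg, g_co, g_og])
    site_class = np.concatenate(
        [
            np.repeat("div", n_div), np.repeat("cg", n_cg),
            np.repeat("co", n_co), np.repeat("og", n_og),
        ]
    ).astype(object)
    order = np.argsort(pos_global, kind="stable")
    pos_global, site_class = pos_global[order], site_class[order]
    S = len(pos_global)

    # ancestral allele is ref (0) everywhere; derived allele is alt (1)
    co_haps = np.zeros((n_hap_co, S), dtype=np.int8)
    cg_haps = np.zeros((n_hap_cg, S), dtype=np.int8)
    og_hap = np.zeros((1, S), dtype=np.int8)

    is_div = site_class == "div"
    side = r_div.random(is_div.sum()) < 0.5  # True: derived fixed in CO lineage
    div_idx = np.flatnonzero(is_div)
    co_haps[:, div_idx[side]] = 1
    cg_haps[:, div_idx[~side]] = 1

    cg_idx = np.flatnonzero(site_class == "cg")
    if len(cg_idx):
        counts = _sfs_counts(r_cg, n_hap_cg, len(cg_idx))
        cg_haps[:, cg_idx] = _assign_derived(r_cg, n_hap_cg, counts)
    co_idx = np.flatnonzero(site_class == "co")
    if len(co_idx):
        counts = _sfs_counts(r_co, n_hap_co, len(co_idx))
        co_haps[:, co_idx] = _assign_derived(r_co, n_hap_co, counts)
    og_hap[0, site_class == "og"] = 1

    scafs, local = _global_to_scaffold(pos_global, params)
    ref, alt = _random_ref_alt(r_emit, S)

    co_gt = (2 * co_haps).astype(np.int8)  # selfer: hom everywhere
    cg_gt = (cg_haps[0::2] + cg_haps[1::2]).astype(np.int8)
    co_gt, co_dp = _apply_missing_and_depth(r_emit, co_gt, params)
    cg_gt, cg_dp = _apply_missing_and_depth(r_emit, cg_gt, params)

    co_names = [f"CO_{i + 1}" for i in range(params.n_co_samples)]
    cg_names = [f"CG_{i + 1}" for i in range(params.n_cg_samples)]
    co_panel = GenotypeMatrix(co_names, scafs, local, ref, alt, co_gt, depth=co_dp)
    cg_panel = GenotypeMatrix(cg_names, scafs, local, ref, alt, cg_gt, depth=cg_dp)
    outgroup = HaplotypeAlignment(["OUT_1"], scafs, local, ref, alt, og_hap)

    return ParentalPanels(
        params=params,
        scaffolds=scafs, positions=local, pos_global=pos_global, ref=ref, alt=alt,
        co_panel=co_panel, cg_panel=cg_panel, outgroup=outgroup,
        co_panel_haps=co_haps, cg_panel_haps=cg_haps, site_class=site_class,
        _pos_pool=pos_pool, _pool_cursor=cursor,
    )


def _place_tracts(rng, L: int, target_bp: float, mean_len: float) -> list[tuple[int, int]]:
    """Place non-overlapping exponential-length tracts totalling ~target_bp."""
    tracts: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target_bp and attempts < 1000:
        attempts += 1
        ln = max(1, int(rng.exponential(mean_len)))
        ln = min(ln, int(target_bp - covered) + 1, L)
        s = int(rng.integers(0, max(1, L - ln)))
        e = s + ln
        if any(not (e <= ts or s >= te) for ts, te in tracts):
            continue
        tracts.append((s, e))
        covered += ln
    return sorted(tracts)


def simulate_tetraploids(panels: ParentalPanels, params: SimParams | None = None):
    """Build three tetraploid populations from the parental panels.

    Each accession carries one internally homozygous haplotype per
    subgenome (disomic selfing).  Populations are differentiated by
    private fixed mutations; accessions add a small amount of private
    variation.  Admixture tracts copy a donor-panel haplotype into the
    requested subgenome over the requested genome fraction.  The emitted
    unphased genotype is heterozygous exactly where the two subgenome
    alleles differ (before missingness is applied).

    Returns ``(unphased GenotypeMatrix, TruthSet)``.
    """
    params = params or panels.params
    ss = np.random.SeedSequence((params.seed, 1))
    r_founder, r_mut, r_tract, r_emit = [np.random.default_rng(s) for s in ss.spawn(4)]

    L = params.seq_length
    pool = panels._pos_pool
    cursor = panels._pool_cursor

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + n]
        cursor += n
        return out

    n_acc = params.n_accessions_per_pop * len(POPULATIONS)
    accessions = [
        f"{pop}_{i + 1}" for pop in POPULATIONS for i in range(params.n_accessions_per_pop)
    ]
    populations = [a.split("_")[0] for a in accessions]

    # new mutation sites: population-private and accession-private, per subgenome
    new_global, new_owner = [], []  # owner: (kind, pop_or_acc_index, subgenome)
    for pi, pop in enumerate(POPULATIONS):
        for sg in ("co", "cg"):
            n = r_mut.binomial(L, params.pop_divergence)
            new_global.append(take(n))
            new_owner += [("pop", pi, sg)] * n
    for ai in range(n_acc):
        for sg in ("co", "cg"):
            n = r_mut.binomial(L, params.accession_theta)
            new_global.append(take(n))
            new_owner += [("acc", ai, sg)] * n
    new_global = np.concatenate(new_global) if new_global else np.array([], dtype=int)

    all_global = np.concatenate([panels.pos_global, new_global])
    order = np.argsort(all_global, kind="stable")
    all_global = all_global[order]
    S = len(all_global)
    old_S = len(panels.pos_global)
    # column index of each original/new site in the combined table
    col_of = np.empty(S, dtype=np.int64)
    col_of[order] = np.arange(S)
    old_cols, new_cols = col_of[:old_S], col_of[old_S:]

    co_haps = np.zeros((n_acc, S), dtype=np.int8)
    cg_haps = np.zeros((n_acc, S), dtype=np.int8)

    founder_co = r_founder.integers(0, panels.co_panel_haps.shape[0], size=len(POPULATIONS))
    founder_cg = r_founder.integers(0, panels.cg_panel_haps.shape[0], size=len(POPULATIONS))
    for ai, pop in enumerate(populations):
        pi = POPULATIONS.index(pop)
        co_haps[ai, old_cols] = panels.co_panel_haps[founder_co[pi]]
        cg_haps[ai, old_cols] = panels.cg_panel_haps[founder_cg[pi]]
    for (kind, owner, sg), col in zip(new_owner, new_cols):
        tgt = co_haps if sg == "co" else cg_haps
        if kind == "pop":
            rows = [ai for ai, p in enumerate(populations) if p == POPULATIONS[owner]]
            tgt[rows, col] = 1
        else:
            tgt[owner, col] = 1

    # admixture tracts
    tract_rows = []
    donor_pool = {"CO": panels.co_panel_haps, "CG": panels.cg_panel_haps}
    for pop, subgenome, donor, fraction in params.admixture_tracts:
        if fraction > 1.0:
            raise SimParamError("tract fraction > 1")
        donor_haps = donor_pool[donor.upper()]
        for ai, p in enumerate(populations):
            if p != pop:
                continue
            tracts = _place_tracts(r_tract, L, fraction * L, params.tract_length_mean)
            donor_hap = donor_haps[r_tract.integers(0, donor_haps.shape[0])]
            donor_full = np.zeros(S, dtype=np.int8)
            donor_full[old_cols] = donor_hap  # donor carries no tetraploid-private alleles
            tgt = co_haps if subgenome.lower() == "co" else cg_haps
            for s, e in tracts:
                in_tract = (all_global >= s) & (all_global < e)
                tgt[ai, in_tract] = donor_full[in_tract]
                tract_rows.append((accessions[ai], subgenome.lower(), donor.upper(), s, e))

    scafs, local = _global_to_scaffold(all_global, params)
    ref = np.empty(S, dtype=object)
    alt = np.empty(S, dtype=object)
    ref[old_cols], alt[old_cols] = panels.ref, panels.alt
    nref, nalt = _random_ref_alt(r_emit, len(new_cols))
    ref[new_cols], alt[new_cols] = nref, nalt

    gt = (co_haps + cg_haps).astype(np.int8)
    gt[co_haps != cg_haps] = 1
    gt[(co_haps == 1) & (cg_haps == 1)] = 2
    gt, depth = _apply_missing_and_depth(r_emit, gt, params)

    unphased = GenotypeMatrix(accessions, scafs, local, ref, alt, gt, depth=depth)

    tracts_df = pd.DataFrame(
        tract_rows, columns=["accession", "subgenome", "donor", "start", "end"]
    )
    if len(tracts_df):
        t_scaf, t_s = _global_to_scaffold(tracts_df["start"].to_numpy(), params)
        _, t_e = _global_to_scaffold(tracts_df["end"].to_numpy() - 1, params)
        tracts_df["scaffold"] = t_scaf
        tracts_df["local_start"] = t_s - 1
        tracts_df["local_end"] = t_e
    else:
        tracts_df["scaffold"] = []
        tracts_df["local_start"] = []
        tracts_df["local_end"] = []

    truth = TruthSet(
        accessions=accessions, populations=populations,
        scaffolds=scafs, positions=local, pos_global=all_global, ref=ref, alt=alt,
        co_haps=co_haps, cg_haps=cg_haps, tracts=tracts_df,
    )
    return unphased, truth


def emit_fragments(truth: TruthSet, unphased: GenotypeMatrix, params: SimParams):
    """Cut each accession's heterozygous sites into phased fragments.

    Fragment boundaries follow exponential block lengths with coverage
    gaps between blocks; each block's A/B labelling is random; a fraction
    ``chimera_rate`` of multi-site blocks has a random suffix phase-flipped
    (a switch error); ``fv_rate`` of sites are flagged invalid.  Truth
    bookkeeping (which blocks were flipped/chimeric) is stored on
    ``truth.fragment_truth``.
    """
    from .phasing import PhasedFragment

    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 2)))
    fragments: list[PhasedFragment] = []
    book = []
    for ai, acc in enumerate(truth.accessions):
        het = (unphased.gt[ai] == 1) & (truth.co_haps[ai] != truth.cg_haps[ai])
        for scaf in pd.unique(truth.scaffolds):
            sel = np.flatnonzero(het & (truth.scaffolds == scaf))
            if len(sel) == 0:
                continue
            pos = truth.positions[sel]
            cur = float(pos[0])
            block_id = 0
            while cur <= pos[-1]:
                blk_len = rng.exponential(params.fragment_length_mean)
                idx = np.flatnonzero((pos >= cur) & (pos < cur + blk_len))
                cur += blk_len + rng.exponential(params.gap_length_mean)
                if len(idx) == 0:
                    continue
                cols = sel[idx]
                states = truth.co_haps[ai, cols].copy()  # hapA carries the Co allele...
                flipped = bool(rng.random() < 0.5)
                if flipped:  # ...unless the block labels A/B the other way round
                    states = 1 - states
                chimeric = False
                breakpoint_ = -1
                if len(cols) >= 2 and rng.random() < params.chimera_rate:
                    breakpoint_ = int(rng.integers(1, len(cols)))
                    states[breakpoint_:] = 1 - states[breakpoint_:]
                    chimeric = True
                fv = rng.random(len(cols)) < params.fv_rate
                fragments.append(
                    PhasedFragment(
                        accession=acc, scaffold=str(scaf),
                        positions=truth.positions[cols].copy(),
                        states=states.astype(np.int8), fv=fv,
                    )
                )
                book.append((acc, str(scaf), block_id, len(cols), flipped, chimeric, breakpoint_))
                block_id += 1
    truth.fragment_truth = pd.DataFrame(
        book,
        columns=["accession", "scaffold", "block", "n_sites", "flipped", "chimeric", "breakpoint"],
    )
    return fragments


# ---------------------------------------------------------------------------
# DNA/RNA allele counts for homeolog-specific expression


def _betabin(rng, n: np.ndarray, mu: np.ndarray, rho: float) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(n, mu)
    nu = 1.0 / rho - 1.0
    p = rng.beta(np.maximum(mu * nu, 1e-9), np.maximum((1 - mu) * nu, 1e-9))
    return rng.binomial(n, p)


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_counts(truth: TruthSet, params: SimParams) -> pd.DataFrame:
    """Per-accession, per-gene, per-SNP DNA and RNA allele counts.

    Toy gene models tile the genome; a gene is assayable if it contains at
    least one site where the two subgenome alleles differ in every
    accession carrying it (an inter-subgenome diagnostic SNP).  DNA counts
    are beta-binomial around 0.5 (dispersion ``rho_dna``) except for a
    fraction of mapping-biased SNPs centered off 0.5 (the bias also
    perturbs RNA counts, as a mapping artifact would).  RNA counts are
    beta-binomial around the gene's true Co/Total ratio: 0.5 for non-HSE
    genes, drawn from ``hse_effect`` for the ``hse_fraction`` of genes with
    true homeolog-specific expression.  Genes without a diagnostic SNP are
    excluded and logged in ``truth.hse_genes``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 3)))
    L = params.seq_length
    gene_span = L // params.n_genes
    diag = np.flatnonzero(np.all(truth.co_haps != truth.cg_haps, axis=0))
    gene_of_site = truth.pos_global[diag] // gene_span

    gene_rows, count_rows = [], []
    biased = []
    for g in range(params.n_genes):
        sites = diag[gene_of_site == g]
        # restrict to SNPs inside the CDS portion of the gene model
        start = g * gene_span
        in_cds = truth.pos_global[sites] < start + params.gene_length
        sites = sites[in_cds][: params.max_snps_per_gene]
        is_hse = bool(rng.random() < params.hse_fraction)
        true_ratio = float(rng.choice(params.hse_effect)) if is_hse else 0.5
        gene_rows.append((f"gene_{g + 1}", len(sites), is_hse, true_ratio))
        if len(sites) == 0:
            continue
        for s in sites:
            snp_biased = bool(rng.random() < params.biased_snp_fraction)
            bias_logit = 0.0
            if snp_biased:
                mag = rng.uniform(_logit(0.65), _logit(0.95))
                bias_logit = mag if rng.random() < 0.5 else -mag
                biased.append((f"gene_{g + 1}", int(truth.positions[s])))
            mu_dna = _expit(bias_logit)
            mu_rna = _expit(_logit(true_ratio) + bias_logit)
            for acc in truth.accessions:
                n_d = rng.poisson(params.dna_depth)
                n_r = rng.poisson(params.rna_depth)
                d_co = _betabin(rng, n_d, mu_dna, params.rho_dna) if n_d else 0
                r_co = _betabin(rng, n_r, mu_rna, params.rho_rna) if n_r else 0
                count_rows.append(
                    (acc, f"gene_{g + 1}", f"{truth.scaffolds[s]}:{truth.positions[s]}",
                     int(d_co), int(n_d - d_co), int(r_co), int(n_r - r_co))
                )
    truth.hse_genes = pd.DataFrame(
        gene_rows, columns=["gene", "n_snps", "is_hse", "true_ratio"]
    )
    excluded = truth.hse_genes[truth.hse_genes.n_snps == 0]
    if len(excluded):
        warnings.warn(f"{len(excluded)} genes without diagnostic SNPs excluded")
    truth.biased_snps = pd.DataFrame(biased, columns=["gene", "position"])
    return pd.DataFrame(
        count_rows,
        columns=["accession", "gene", "snp", "dna_co", "dna_cg", "rna_co", "rna_cg"],
    )


def write_gene_models(params: SimParams, path: str) -> None:
    """Toy single-CDS gene models tiling the genome, as GFF3 (+ strand)."""
    ls = params.scaffold_length()
    gene_span = params.seq_length // params.n_genes
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in range(params.n_genes):
            start = g * gene_span  # global, 0-based
            end = start + params.gene_length
            scaf_i = start // ls
            if end > (scaf_i + 1) * ls:  # keep toy genes within one scaffold
                end = (scaf_i + 1) * ls
            name = params.scaffold_names()[min(scaf_i, params.n_scaffolds - 1)]
            s_local = start - scaf_i * ls + 1
            e_local = end - scaf_i * ls
            gid = f"gene_{g + 1}"
            fh.write(f"{name}\thomeokit\tgene\t{s_local}\t{e_local}\t.\t+\t.\tID={gid}\n")
            fh.write(
                f"{name}\thomeokit\tCDS\t{s_local}\t{e_local}\t.\t+\t0\t"
                f"ID={gid}.cds;Parent={gid}\n"
            )


# ---------------------------------------------------------------------------
# Coalescent backend (msprime)


def coalescent_subgenomes(
    n_accessions: int = 30,
    seq_length: int = 2_000_000,
    ne: float = 50_000,
    recomb: float = 1e-8,
    mu: float = 7e-9,
    seed: int = 0,
):
    """Two independent coalescent subgenome alignments for the same accessions.

    Each subgenome is a single panmictic population sampled as one
    haplotype per accession; sites of the two subgenomes are disjoint and
    interleave along the same coordinate system.  Because the two tree
    sequences are independent there is linkage disequilibrium within, but
    not between, subgenomes -- the structure the LD-decay validation relies
    on.  Returns ``(co_alignment, cg_alignment)``.
    """
    import msprime

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1) + 1) for s in ss.spawn(4)]
    out = []
    for k, label in enumerate(("Co", "Cg")):
        ts = msprime.sim_ancestry(
            samples=n_accessions, ploidy=1, population_size=ne,
            sequence_length=seq_length, recombination_rate=recomb,
            random_seed=seeds[2 * k],
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=seeds[2 * k + 1], model=msprime.BinaryMutationModel()
        )
        pos = np.array([int(v.site.position) + 1 for v in ts.variants()])
        gm = ts.genotype_matrix().T.astype(np.int8)  # haps x sites
        gm[gm > 1] = 1
        keep = np.concatenate([[True], np.diff(pos) > 0])
        pos, gm = pos[keep], gm[:, keep]
        names = [f"acc_{i + 1}_{label}" for i in range(n_accessions)]
        ref = np.repeat("A", len(pos)).astype(object)
        alt = np.repeat("T", len(pos)).astype(object)
        out.append(
            HaplotypeAlignment(
                names, np.repeat("scaffold_1", len(pos)).astype(object), pos, ref, alt, gm
            )
        )
    return tuple(out)


def simulate_quartet_frequencies(
    n_replicates: int = 200,
    seq_length: int = 500_000,
    n_per_pop: int = 10,
    ne: float = 10_000,
    t1: float = 10_000,
    t2: float = 20_000,
    t3: float = 100_000,
    mu: float = 7e-9,
    recomb: float = 1e-8,
    replace_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Coalescent replicates of (((P1,P2),P3),O) for ABBA-BABA calibration.

    Symmetric neutral model with no post-split migration; population joins
    at ``t1`` (P1+P2), ``t2`` (+P3) and ``t3`` (+outgroup) generations.
    ``replace_fraction`` alpha swaps ``round(alpha * n_per_pop)`` of the P2
    sample for extra haplotypes drawn from the P3 population, emulating
    admixture by complete lineage replacement of that fraction of the
    genome.  Returns one row per segregating site with columns
    ``chrom, pos, p1, p2, p3, po`` (allele frequencies of the derived
    state per population) suitable for :mod:`homeokit.introgression`.
    """
    import msprime

    k_rep = int(round(replace_fraction * n_per_pop))
    demography = msprime.Demography()
    for name in ("P1", "P2", "P3", "OUT"):
        demography.add_population(name=name, initial_size=ne)
    for name in ("A12", "A123", "ROOT"):
        demography.add_population(name=name, initial_size=ne)
    demography.add_population_split(time=t1, derived=["P1", "P2"], ancestral="A12")
    demography.add_population_split(time=t2, derived=["A12", "P3"], ancestral="A123")
    demography.add_population_split(time=t3, derived=["A123", "OUT"], ancestral="ROOT")

    samples = [
        msprime.SampleSet(n_per_pop, population="P1", ploidy=1),
        msprime.SampleSet(n_per_pop - k_rep, population="P2", ploidy=1),
        msprime.SampleSet(n_per_pop + k_rep, population="P3", ploidy=1),
        msprime.SampleSet(n_per_pop, population="OUT", ploidy=1),
    ]
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**30)) + 1
    anc_reps = msprime.sim_ancestry(
        samples=samples, demography=demography, sequence_length=seq_length,
        recombination_rate=recomb, num_replicates=n_replicates, random_seed=base,
    )
    rows = []
    i1 = slice(0, n_per_pop)
    i2 = slice(n_per_pop, 2 * n_per_pop)  # (true P2 remainder + replacement P3 haps)
    i3 = slice(2 * n_per_pop, 3 * n_per_pop)
    io = slice(3 * n_per_pop, 4 * n_per_pop)
    for rep, ts in enumerate(anc_reps):
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=base + rep + 1, model=msprime.BinaryMutationModel()
        )
        if ts.num_sites == 0:
            continue
        gm = ts.genotype_matrix()
        gm[gm > 1] = 1
        pos = np.array([int(v.position) + 1 for v in ts.sites()])
        p1 = gm[:, i1].mean(axis=1)
        p2 = gm[:, i2].mean(axis=1)
        p3 = gm[:, i3].mean(axis=1)
        po = gm[:, io].mean(axis=1)
        rows.append(
            pd.DataFrame(
                {"chrom": f"rep_{rep}", "pos": pos, "p1": p1, "p2": p2, "p3": p3, "po": po}
            )
        )
    return pd.concat(rows, ignore_index=True)
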