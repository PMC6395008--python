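"""End-to-end pipeline orchestration and configuration.

A :class:`PipelineConfig` (YAML round-trippable) drives the stage chain
simulate -> filter -> phase -> {popstats, ld, trees, abba, hse}; every
stage can also be run standalone through the library with identical
results.  A manifest records the seed, per-stage row counts, and sha256
checksums of all outputs so a rerun with the same config can be verified
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("homeokit")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # inputs (ignored when simulate=True, which generates them)
    vcf: str | None = None
    fragments: str | None = None
    parent_co_vcf: str | None = None
    parent_cg_vcf: str | None = None
    counts: str | None = None
    mask_bed: str | None = None
    # thresholds (defaults mirror the documented filter cascade)
    min_depth: int = 6
    max_depth: int = 100
    max_missing: float = 0.8
    diag_max_missing: float = 0.2
    min_informative: int = 2
    min_consistency: float = 0.9
    window_bp: int = 100_000
    n_boot: int = 10_000
    block_bp: int = 1_000_000
    hse_iters: int = 200_000
    hse_burnin: int = 20_000
    hse_thin: int = 100
    hse_chains: int = 3
    hse_threshold: float = 0.99
    # simulation
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # overrides for sim.SimParams
    seed: int = 0
    outdir: str = "homeokit_out"

    def validate(self) -> None:
        if not 0 <= self.max_missing <= 1 or not 0 <= self.diag_max_missing <= 1:
            raise ConfigError("missingness thresholds must lie in [0,1]")
        if not 0.5 <= self.min_consistency <= 1:
            raise ConfigError("min_consistency must lie in [0.5, 1]")
        if not self.simulate:
            for name in ("vcf", "fragments", "parent_co_vcf", "parent_cg_vcf"):
                if getattr(self, name) is None:
                    raise ConfigError(f"{name} is required unless simulate is set")

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stage chain and return the manifest (also written to disk)."""
    from . import hse as hse_mod
    from . import ld, phasing, popstats, sim, trees, variants

    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    try:
        if config.simulate:
            params = sim.SimParams(seed=config.seed, **config.sim)
            panels = sim.simulate_parental_panels(params)
            unphased, truth = sim.simulate_tetraploids(panels, params)
            fragments = sim.emit_fragments(truth, unphased, params)
            counts = sim.simulate_counts(truth, params)
            variants.write_vcf(unphased, str(out / "tetraploids.vcf"))
            variants.write_vcf(panels.co_panel, str(out / "parent_co.vcf"))
            variants.write_vcf(panels.cg_panel, str(out / "parent_cg.vcf"))
            phasing.write_fragments(fragments, str(out / "fragments.txt"))
            counts.to_csv(out / "counts.tsv", sep="\t", index=False)
            truth.tracts_to_bed(str(out / "truth_tracts.bed"))
            truth.co_alignment().to_fasta(str(out / "truth_co.fasta"))
            truth.cg_alignment().to_fasta(str(out / "truth_cg.fasta"))
            sim.write_gene_models(params, str(out / "genes.gff"))
            panel_co, panel_cg = panels.co_panel, panels.cg_panel
            outgroup = panels.outgroup
            record(
                "simulate", n_sites=int(unphased.n_sites), n_accessions=unphased.n_samples,
                n_fragments=len(fragments), n_count_rows=len(counts),
            )
        else:
            unphased = variants.read_genotypes(config.vcf)
            panel_co = variants.read_genotypes(config.parent_co_vcf)
            panel_cg = variants.read_genotypes(config.parent_cg_vcf)
            fragments = phasing.read_fragments(config.fragments)
            counts = (
                pd.read_csv(config.counts, sep="\t") if config.counts else None
            )
            outgroup = None
            record("load", n_sites=int(unphased.n_sites), n_fragments=len(fragments))

        # filter
        before = unphased.n_sites
        unphased = variants.filter_genotypes(unphased, config.min_depth, config.max_depth)
        unphased = variants.filter_missingness(unphased, config.max_missing)
        if config.mask_bed:
            unphased = variants.apply_mask(unphased, variants.SiteMask.from_bed(config.mask_bed))
        record("filter", sites_in=before, sites_out=int(unphased.n_sites))

        # phase
        diag = phasing.find_diagnostic_sites(panel_co, panel_cg, config.diag_max_missing)
        aln = phasing.assemble_subgenomes(
            fragments, unphased, diag, seed=config.seed,
            min_informative=config.min_informative, min_consistency=config.min_consistency,
        )
        phasing.phasing_report(aln).to_csv(out / "phasing_qc.tsv", sep="\t", index=False)
        phasing.write_phased_vcf(aln, str(out / "phased.vcf"))
        record("phase", n_diagnostic=len(diag), mean_q=float(aln.stats["q_missing"].mean()))

        # popstats
        co_aln, cg_aln = aln.co_alignment(), aln.cg_alignment()
        pi_co = popstats.window_pi(co_aln, config.window_bp)
        pi_cg = popstats.window_pi(cg_aln, config.window_bp)
        dxy = popstats.window_dxy(co_aln, cg_aln, config.window_bp)
        pd.concat(
            [pi_co.assign(stat="pi_co"), pi_cg.assign(stat="pi_cg"), dxy.assign(stat="dxy")]
        ).to_csv(out / "windows.tsv", sep="\t", index=False)
        p_boot = popstats.bootstrap_compare(pi_co, pi_cg, config.n_boot, config.seed)
        record("popstats", n_windows=len(pi_co), pi_ratio_p=p_boot)

        # ld validation
        profiles = []
        for scheme in ("within-co", "within-cg", "between", "random-mix"):
            profiles.append(
                ld.ld_decay_profile(
                    co_aln, cg_aln, scheme,
                    n_principal=100, n_next=300, n_bins=50, seed=config.seed,
                )
            )
        pd.concat(profiles).to_csv(out / "ld_profiles.tsv", sep="\t", index=False)
        record("ld", n_profiles=len(profiles))

        # trees + topology weights on a combined alignment (needs outgroup)
        if outgroup is not None:
            og = _reindex_outgroup(outgroup, co_aln)
            combined = _combine([co_aln, cg_aln, og])
            windows, skipped = trees.sliding_trees(combined, config.window_bp, 20)
            with open(out / "trees.nwk", "w") as fh:
                for scaf, s, e, t in windows:
                    fh.write(f"{scaf}\t{s}\t{e}\t{t.to_newick()}\n")
            record("trees", n_trees=len(windows), n_skipped=skipped)

        # abba-baba on phased subgenomes is only meaningful with population maps;
        # emit frequencies for the three populations of the Co subgenome vs parents
        record("abba", note="run `homeokit abba` with a population map for D/f tests")

        # hse
        if counts is not None and len(counts):
            t = hse_mod.prepare_table(counts)
            t, removed = hse_mod.filter_biased_snps(t)
            disp = hse_mod.fit_dna_dispersion(t)
            params_h = hse_mod.HSEModelParams(
                n_iter=config.hse_iters, burn_in=config.hse_burnin,
                thin=config.hse_thin, n_chains=config.hse_chains, seed=config.seed,
            )
            pooled = t.groupby(["gene", "snp"], as_index=False)[
                ["dna_co", "dna_cg", "rna_co", "rna_cg"]
            ].sum()
            res = hse_mod.fit_rna_model(pooled, disp["rho"], params_h)
            fdr, sig = hse_mod.bayesian_fdr(
                res["posterior_prob_hse"].to_numpy(), config.hse_threshold
            )
            res["significant"] = sig
            res.to_csv(out / "hse_results.tsv", sep="\t", index=False)
            record(
                "hse", n_genes=len(res), n_significant=int(sig.sum()),
                fdr=None if np.isnan(fdr) else float(fdr),
                rho_dna=disp["rho"], n_removed_snps=len(removed),
            )
    except Exception as e:
        manifest["failed_stage"] = _last_stage(manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed after stage {_last_stage(manifest)}: {e}") from e

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["checksums"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _last_stage(manifest: dict) -> str:
    stages = list(manifest["stages"])
    return stages[-1] if stages else "(none)"


def _reindex_outgroup(outgroup, target):
    """Project the outgroup haplotype onto a (super)set site table.

    Sites absent from the outgroup's table take the reference (ancestral)
    allele, which is what the generator's infinite-sites model implies.
    """
    from .variants import HaplotypeAlignment

    have = {
        (s, int(p)): outgroup.haps[0, j]
        for j, (s, p) in enumerate(zip(outgroup.scaffolds, outgroup.positions))
    }
    haps = np.zeros((1, target.n_sites), dtype=np.int8)
    for j, (s, p) in enumerate(zip(target.scaffolds, target.positions)):
        haps[0, j] = have.get((s, int(p)), 0)
    return HaplotypeAlignment(
        list(outgroup.names), target.scaffolds, target.positions, target.ref, target.alt, haps
    )


def _combine(alns):
    """Stack alignments sharing a site table into one."""
    from .variants import HaplotypeAlignment

    first = alns[0]
    names = [n for a in alns for n in a.names]
    haps = np.vstack([a.haps for a in alns])
    return HaplotypeAlignment(
        names, first.scaffolds, first.positions, first.ref, first.alt, haps
    )
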