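"""Homeolog-specific expression (HSE) via a DNA-calibrated Bayesian model.

Gene expression of the two subgenome copies is compared from RNA allele
counts at inter-subgenome diagnostic SNPs.  Genomic DNA counts, which
should split 50/50, first identify mapping-biased SNPs (removed) and
calibrate the technical overdispersion of counts around 0.5.  RNA counts
are then modelled per gene as a two-component mixture: under H0 the gene's
Co/Total ratio is 0.5 and SNP counts are beta-binomial with the
DNA-estimated dispersion; under H1 the gene ratio is drawn from a
logit-normal prior and SNP counts disperse around it with an additional
RNA-level dispersion estimated jointly.  A per-gene indicator with a
shared mixing fraction is sampled by Metropolis-within-Gibbs MCMC; its
posterior mean is the posterior probability of HSE, thresholded (default
0.99) with a Bayesian false-discovery-rate estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import betaln, expit


class HSEError(ValueError):
    pass


MIN_RNA_COVERAGE = 10  # SNP calls below this total RNA depth are excluded


@dataclass
class HSEModelParams:
    """MCMC and prior settings for the RNA mixture model."""

    n_iter: int = 200_000
    burn_in: int = 20_000
    thin: int = 100
    n_chains: int = 3
    phi_init: float = 0.1  # initial HSE mixing fraction (estimated jointly)
    sigma_scale: float = 1.5  # half-normal hyperprior scale for the logit-ratio SD
    rho_rna_scale: float = 0.05  # half-normal prior scale for extra RNA dispersion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise HSEError("burn_in must be smaller than n_iter")
        if not 0 <= self.phi_init <= 1:
            raise HSEError("phi_init outside [0,1]")


def prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the count-level RNA filter: total RNA coverage >= 10 per SNP call."""
    t = table.copy()
    keep = (t["rna_co"] + t["rna_cg"]) >= MIN_RNA_COVERAGE
    return t[keep].reset_index(drop=True)


def filter_biased_snps(
    table: pd.DataFrame, dna_threshold: float = 1e-6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove SNPs whose DNA counts deviate strongly from the 0.5 mapping ratio.

    DNA counts are pooled per (gene, snp) across accessions and tested
    two-sided against a binomial(0.5); SNPs with tail probability below
    ``dna_threshold`` -- or zero pooled depth -- are removed.  Returns
    ``(retained rows, removed summary)``.
    """
    pooled = table.groupby(["gene", "snp"], sort=False).agg(
        dna_co=("dna_co", "sum"), dna_cg=("dna_cg", "sum")
    )
    n = (pooled["dna_co"] + pooled["dna_cg"]).to_numpy()
    k = pooled["dna_co"].to_numpy()
    with np.errstate(invalid="ignore"):
        lo = sps.binom.cdf(k, np.maximum(n, 1), 0.5)
        hi = sps.binom.sf(k - 1, np.maximum(n, 1), 0.5)
        p = np.minimum(1.0, 2 * np.minimum(lo, hi))
    remove = (p < dna_threshold) | (n == 0)
    pooled = pooled.assign(p_binom=p, removed=remove)
    bad = set(pooled.index[remove])
    keep_rows = ~table.set_index(["gene", "snp"]).index.isin(bad)
    return table[keep_rows].reset_index(drop=True), pooled[pooled.removed].reset_index()


def fit_dna_dispersion(table: pd.DataFrame) -> dict:
    """ML beta-binomial overdispersion of DNA counts with mean fixed at 0.5.

    The dispersion is the intraclass correlation rho in (0, 1); the
    beta-binomial concentration is nu = 1/rho - 1.  Returns the estimate,
    a normal-approximation SE/CI, and a boundary flag when the estimate
    collapses to the binomial limit.
    """
    k = table["dna_co"].to_numpy(float)
    n = (table["dna_co"] + table["dna_cg"]).to_numpy(float)
    ok = n > 0
    k, n = k[ok], n[ok]
    if len(k) < 10:
        raise HSEError("need >= 10 SNP observations to estimate DNA dispersion")

    def nll(log_rho: float) -> float:
        rho = np.exp(log_rho)
        a = 0.5 * (1.0 / rho - 1.0)
        return -np.sum(betaln(k + a, n - k + a) - betaln(a, a))

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-8), np.log(0.5)), method="bounded")
    log_rho = res.x
    rho = float(np.exp(log_rho))
    h = 1e-4
    d2 = (nll(log_rho + h) - 2 * nll(log_rho) + nll(log_rho - h)) / h**2
    se_log = float(np.sqrt(1.0 / d2)) if d2 > 0 else np.nan
    boundary = rho < 1e-6
    if boundary:
        warnings.warn("DNA dispersion at the binomial boundary (no overdispersion detected)")
    return dict(
        rho=rho,
        se_log=se_log,
        ci=(float(np.exp(log_rho - 1.96 * se_log)), float(np.exp(log_rho + 1.96 * se_log)))
        if np.isfinite(se_log)
        else (np.nan, np.nan),
        boundary=boundary,
        mean_ratio=float(np.mean(k / n)),
        n_snps=len(k),
    )


def _betabin_loglik(y, n, mu, nu):
    """Beta-binomial log-likelihood without the binomial coefficient (cancels in ratios)."""
    a = np.maximum(mu * nu, 1e-10)
    b = np.maximum((1 - mu) * nu, 1e-10)
    return betaln(y + a, n - y + b) - betaln(a, b)


def _half_normal_logpdf(x, scale):
    return -0.5 * (x / scale) ** 2


@dataclass
class _GeneData:
    genes: list[str]
    y: np.ndarray  # G x Kmax RNA co counts (padded)
    n: np.ndarray  # G x Kmax RNA totals
    mask: np.ndarray  # G x Kmax validity


def _pack(table: pd.DataFrame) -> _GeneData:
    genes = list(dict.fromkeys(table["gene"]))
    kmax = int(table.groupby("gene", sort=False).size().max())
    G = len(genes)
    y = np.zeros((G, kmax))
    n = np.zeros((G, kmax))
    mask = np.zeros((G, kmax), dtype=bool)
    for gi, (g, grp) in enumerate(table.groupby("gene", sort=False)):
        m = len(grp)
        y[gi, :m] = grp["rna_co"].to_numpy()
        n[gi, :m] = (grp["rna_co"] + grp["rna_cg"]).to_numpy()
        mask[gi, :m] = True
    return _GeneData(genes, y, n, mask)


def _run_chain(data: _GeneData, rho_dna: float, params: HSEModelParams, seed: int):
    rng = np.random.default_rng(seed)
    G = len(data.genes)
    y, n, mask = data.y, data.n, data.mask

    nu0 = 1.0 / max(rho_dna, 1e-8) - 1.0
    ll0 = np.where(mask, _betabin_loglik(y, n, 0.5, nu0), 0.0).sum(axis=1)  # constant

    def ll1(lam, rho_rna):
        mu = expit(lam)[:, None]
        nu1 = 1.0 / np.minimum(rho_dna + rho_rna, 0.999) - 1.0
        return np.where(mask, _betabin_loglik(y, n, mu, nu1), 0.0).sum(axis=1)

    # dispersed starts per chain
    lam = rng.normal(0, 0.5, size=G)
    z = rng.random(G) < params.phi_init
    phi = min(max(params.phi_init + rng.normal(0, 0.05), 0.01), 0.99)
    sigma = float(np.abs(rng.normal(1.0, 0.3))) + 0.1
    rho_rna = float(np.abs(rng.normal(params.rho_rna_scale, params.rho_rna_scale / 2))) + 1e-4

    step_lam = np.full(G, 0.5)
    step_sig = 0.3
    step_rho = 0.5
    acc_lam = np.zeros(G)
    cnt_lam = np.zeros(G)
    acc_sig = acc_rho = 0.0

    cur_ll1 = ll1(lam, rho_rna)
    keep_iters = range(params.burn_in, params.n_iter, params.thin)
    n_keep = len(keep_iters)
    z_sum = np.zeros(G)
    ratio_sum = np.zeros(G)
    trace = {"phi": np.empty(n_keep), "sigma": np.empty(n_keep), "rho_rna": np.empty(n_keep)}
    k_out = 0

    hyper_every = 5  # systematic-scan thinning of the hyperparameter updates

    for it in range(params.n_iter):
        # gene log-ratio: MH where z=1; fresh prior draw (pseudo-prior) where z=0
        prop = np.where(z, lam + rng.normal(0, step_lam), rng.normal(0, sigma, size=G))
        new_ll1 = ll1(prop, rho_rna)
        log_acc = (new_ll1 - cur_ll1) - (prop**2 - lam**2) / (2 * sigma**2)
        accept = (~z) | (np.log(rng.random(G)) < log_acc)
        lam = np.where(accept, prop, lam)
        cur_ll1 = np.where(accept, new_ll1, cur_ll1)
        acc_lam += accept & z
        cnt_lam += z

        # gene indicator (Gibbs)
        log_odds = np.log(phi) - np.log1p(-phi) + cur_ll1 - ll0
        z = rng.random(G) < expit(log_odds)

        # mixing fraction (Gibbs, uniform prior)
        k_on = int(z.sum())
        phi = rng.beta(1 + k_on, 1 + G - k_on)

        if it % hyper_every == 0:
            # logit-ratio scale sigma (MH on log sigma, half-normal hyperprior)
            prop_s = sigma * np.exp(rng.normal(0, step_sig))

            def sig_target(s):
                return (
                    -G * np.log(s) - np.sum(lam**2) / (2 * s**2)
                    + _half_normal_logpdf(s, params.sigma_scale) + np.log(s)
                )

            if np.log(rng.random()) < sig_target(prop_s) - sig_target(sigma):
                sigma = prop_s
                acc_sig += 1

            # extra RNA dispersion (MH on log rho)
            prop_r = rho_rna * np.exp(rng.normal(0, step_rho))
            if prop_r < 0.98:
                new_ll1_r = ll1(lam, prop_r)
                num = (
                    np.sum(new_ll1_r[z])
                    + _half_normal_logpdf(prop_r, params.rho_rna_scale) + np.log(prop_r)
                )
                den = (
                    np.sum(cur_ll1[z])
                    + _half_normal_logpdf(rho_rna, params.rho_rna_scale) + np.log(rho_rna)
                )
                if np.log(rng.random()) < num - den:
                    rho_rna = prop_r
                    cur_ll1 = new_ll1_r
                    acc_rho += 1

        # adapt proposal scales during burn-in only
        if it < params.burn_in and (it + 1) % 200 == 0:
            n_h = max(200 // hyper_every, 1)
            rate = acc_lam / np.maximum(cnt_lam, 1)
            step_lam *= np.exp(np.where(cnt_lam > 0, np.clip(rate - 0.44, -0.5, 0.5), 0.0))
            step_lam = np.clip(step_lam, 1e-3, 5.0)
            step_sig *= np.exp(np.clip(acc_sig / n_h - 0.44, -0.5, 0.5))
            step_rho *= np.exp(np.clip(acc_rho / n_h - 0.44, -0.5, 0.5))
            acc_lam[:] = 0
            cnt_lam[:] = 0
            acc_sig = acc_rho = 0.0

        if it >= params.burn_in and (it - params.burn_in) % params.thin == 0:
            z_sum += z
            ratio_sum += np.where(z, expit(lam), 0.5)
            trace["phi"][k_out] = phi
            trace["sigma"][k_out] = sigma
            trace["rho_rna"][k_out] = rho_rna
            k_out += 1

    return dict(
        post_z=z_sum / n_keep,
        post_ratio=ratio_sum / n_keep,
        trace={k: v[:k_out] for k, v in trace.items()},
    )


def _split_rhat(chains: np.ndarray) -> float:
    """Potential scale reduction (split-R-hat) over a (chain, draw) array."""
    import arviz as az

    return float(az.rhat(np.atleast_2d(chains)))


def fit_rna_model(
    table: pd.DataFrame, rho_dna: float, params: HSEModelParams | None = None
) -> pd.DataFrame:
    """Per-gene posterior probability of HSE and posterior mean Co/Total ratio.

    Runs ``n_chains`` MCMC chains from dispersed starts; per-gene
    posteriors average the thinned post-burn-in draws of all chains.
    Convergence of the hyperparameters (mixing fraction, logit-ratio
    scale, RNA dispersion) is reported as split-R-hat; values above 1.1
    flag (not suppress) the result.
    """
    params = params or HSEModelParams()
    if table.groupby("gene").size().min() < 1:
        raise HSEError("every gene needs >= 1 retained SNP")
    data = _pack(table)
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(params.n_chains)]
    runs = [_run_chain(data, rho_dna, params, s) for s in seeds]

    post_z = np.mean([r["post_z"] for r in runs], axis=0)
    post_ratio = np.mean([r["post_ratio"] for r in runs], axis=0)
    rhats = {}
    for h in ("phi", "sigma", "rho_rna"):
        draws = np.vstack([r["trace"][h] for r in runs])
        rhats[h] = _split_rhat(draws) if params.n_chains > 1 else np.nan
    max_rhat = np.nanmax(list(rhats.values())) if params.n_chains > 1 else np.nan
    if params.n_chains > 1 and max_rhat > 1.1:
        warnings.warn(f"MCMC convergence diagnostic above 1.1: {rhats}")

    out = pd.DataFrame(
        {
            "gene": data.genes,
            "posterior_prob_hse": post_z,
            "posterior_ratio": np.clip(post_ratio, 1e-9, 1 - 1e-9),
        }
    )
    out.attrs["rhat"] = rhats
    out.attrs["converged"] = bool(max_rhat <= 1.1) if params.n_chains > 1 else True
    out.attrs["chain_post_z"] = np.array([r["post_z"] for r in runs])
    return out


def bayesian_fdr(posteriors: np.ndarray, threshold: float = 0.99):
    """Bayesian FDR at a posterior threshold: mean(1 - p) over calls above it.

    Returns ``(fdr, boolean significant mask)``; FDR is nan when nothing
    passes the threshold.
    """
    p = np.asarray(posteriors, float)
    if np.any((p < 0) | (p > 1)):
        raise HSEError("posteriors must lie in [0, 1]")
    sig = p > threshold
    fdr = float(np.mean(1.0 - p[sig])) if sig.any() else float("nan")
    return fdr, sig


def ratio_summaries(
    results: pd.DataFrame, population_of: dict[str, str], threshold: float = 0.99
) -> pd.DataFrame:
    """Grand-mean expression ratios per accession and population.

    ``results`` needs columns accession, gene, posterior_prob_hse,
    posterior_ratio (one row per accession-gene).  Reports each
    accession's grand mean over all genes and over significant genes, plus
    population means of those.
    """
    rows = []
    for acc, grp in results.groupby("accession"):
        sig = grp["posterior_prob_hse"] > threshold
        rows.append(
            dict(
                accession=acc,
                population=population_of.get(acc, "?"),
                mean_ratio_all=float(grp["posterior_ratio"].mean()),
                mean_ratio_significant=float(grp.loc[sig, "posterior_ratio"].mean())
                if sig.any()
                else np.nan,
                n_genes=len(grp),
                n_significant=int(sig.sum()),
            )
        )
    per_acc = pd.DataFrame(rows)
    pop = (
        per_acc.groupby("population")
        .agg(
            mean_ratio_all=("mean_ratio_all", "mean"),
            mean_ratio_significant=("mean_ratio_significant", "mean"),
            n_accessions=("accession", "count"),
        )
        .reset_index()
    )
    per_acc.attrs["population_summary"] = pop
    return per_acc
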