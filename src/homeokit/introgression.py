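"""Frequency-based ABBA-BABA statistics with block-jackknife significance.

For a four-taxon arrangement (((P1,P2),P3),O), incomplete lineage sorting
produces ABBA and BABA site patterns at equal expected frequency; gene
flow between P3 and one of P1/P2 skews the balance.  Both pattern classes
are counted from population allele frequencies,

    ABBA = sum (1-p1) p2 p3 (1-pO)      BABA = sum p1 (1-p2) p3 (1-pO),

and summarized as D = (ABBA-BABA)/(ABBA+BABA) and the admixture-fraction
estimate f = S(P1,P2,P3,O)/S(P1,P3,P3,O), the observed ABBA-BABA excess
divided by that expected under complete admixture (the "hom" denominator;
an alternative splits P3 into halves).  Standard errors come from a
delete-one block jackknife over genomic tiles (default 1 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class IntrogressionError(ValueError):
    pass


@dataclass
class DResult:
    statistic: str
    value: float
    se: float
    z: float
    p_value: float
    n_blocks: int


def polarize(freqs: pd.DataFrame) -> pd.DataFrame:
    """Flip allele labels so the outgroup's major allele is ancestral.

    At sites with pO > 0.5 every frequency p becomes 1 - p; a polymorphic
    outgroup then contributes its residual derived frequency directly in
    the pattern products.
    """
    out = freqs.copy()
    flip = out["po"].to_numpy() > 0.5
    for c in ("p1", "p2", "p3", "po"):
        v = out[c].to_numpy(float).copy()
        v[flip] = 1.0 - v[flip]
        out[c] = v
    return out


def assign_blocks(freqs: pd.DataFrame, block_bp: int = 1_000_000) -> pd.Series:
    """Fixed genomic tiles per scaffold; the last partial tile is kept."""
    return (
        freqs["chrom"].astype(str)
        + ":"
        + ((freqs["pos"].to_numpy(np.int64) - 1) // block_bp).astype(str)
    )


def pattern_sums(
    freqs: pd.DataFrame, block_bp: int = 1_000_000, n3: int | None = None
) -> pd.DataFrame:
    """ABBA/BABA (and complete-admixture denominator) sums per block.

    Input columns: chrom, pos, p1, p2, p3, po (derived-allele frequencies;
    run :func:`polarize` first if the outgroup is not yet ancestral).
    Sites where any population frequency is nan are excluded.

    The complete-admixture denominator substitutes P3 for P2 and therefore
    involves the population products p3^2 and p3(1-p3).  When ``n3`` (the
    number of P3 haplotypes behind the frequencies) is given, the
    finite-sample unbiased estimators ``p(np-1)/(n-1)`` and
    ``np(1-p)/(n-1)`` replace the plug-in products; the plug-in denominator
    systematically overshoots by the sampling variance p(1-p)/n and biases
    f downward.  Without ``n3`` the plug-in products are used.
    """
    f = freqs.dropna(subset=["p1", "p2", "p3", "po"])
    p1, p2, p3, po = (f[c].to_numpy(float) for c in ("p1", "p2", "p3", "po"))
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    # denominator patterns with P3 standing in for P2 (complete admixture)
    if n3 is not None and n3 > 1:
        p3_sq = p3 * (n3 * p3 - 1) / (n3 - 1)
        p3_het = n3 * p3 * (1 - p3) / (n3 - 1)
    else:
        p3_sq = p3 * p3
        p3_het = p3 * (1 - p3)
    abba_hom = (1 - p1) * p3_sq * (1 - po)
    baba_hom = p1 * p3_het * (1 - po)
    df = pd.DataFrame(
        {
            "block": assign_blocks(f, block_bp).to_numpy(),
            "abba": abba,
            "baba": baba,
            "abba_hom": abba_hom,
            "baba_hom": baba_hom,
        }
    )
    return df.groupby("block", sort=True).sum()


def pattern_sums_split(freqs: pd.DataFrame, block_bp: int = 1_000_000,
                       p3a: str = "p3a", p3b: str = "p3b") -> pd.DataFrame:
    """Denominator sums for the f_G variant (P3 split into two halves)."""
    f = freqs.dropna(subset=["p1", p3a, p3b, "po"])
    p1, pa, pb, po = (f[c].to_numpy(float) for c in ("p1", p3a, p3b, "po"))
    df = pd.DataFrame(
        {
            "block": assign_blocks(f, block_bp).to_numpy(),
            "abba_g": (1 - p1) * pa * pb * (1 - po),
            "baba_g": p1 * (1 - pa) * pb * (1 - po),
        }
    )
    return df.groupby("block", sort=True).sum()


def d_statistic(sums: pd.DataFrame) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA) from (possibly per-block) sums."""
    abba, baba = float(sums["abba"].sum()), float(sums["baba"].sum())
    denom = abba + baba
    if denom == 0:
        return float("nan")
    return (abba - baba) / denom


def f_statistic(sums: pd.DataFrame, mode: str = "hom") -> float:
    """Admixture fraction f: observed ABBA-BABA excess over the complete-admixture excess."""
    num = float(sums["abba"].sum() - sums["baba"].sum())
    if mode == "hom":
        den = float(sums["abba_hom"].sum() - sums["baba_hom"].sum())
    elif mode == "G":
        if "abba_g" not in sums.columns:
            raise IntrogressionError("f_G requires split-P3 sums (pattern_sums_split)")
        den = float(sums["abba_g"].sum() - sums["baba_g"].sum())
    else:
        raise IntrogressionError(f"unknown f mode {mode!r}")
    if den == 0:
        return float("nan")
    return num / den


def block_jackknife(
    sums: pd.DataFrame, statistic: str = "D", f_mode: str = "hom"
) -> DResult:
    """Delete-one-block jackknife SE, Z-score and two-tailed normal p-value.

    SE = sqrt(((n-1)/n) * sum_j (theta_-j - mean(theta_-))^2) over the n
    delete-one estimates; Z = theta / SE.  A statistic constant across
    blocks yields SE = 0 and an undefined (nan) Z, flagged rather than
    raised.
    """
    if len(sums) < 2:
        raise IntrogressionError("block jackknife requires >= 2 non-empty blocks")
    est = d_statistic if statistic == "D" else (lambda s: f_statistic(s, f_mode))
    theta = est(sums)
    n = len(sums)
    loo = np.array([est(sums.drop(index=b)) for b in sums.index])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    if se == 0 or np.isnan(se):
        return DResult(statistic, theta, se, float("nan"), float("nan"), n)
    z = theta / se
    p = 2 * sps.norm.sf(abs(z))
    return DResult(statistic, theta, se, float(z), float(p), n)


def abba_baba_test(
    freqs: pd.DataFrame,
    block_bp: int = 1_000_000,
    f_mode: str = "hom",
    n3: int | None = None,
) -> pd.DataFrame:
    """Full test: polarize, sum patterns per block, jackknife D and f.

    Returns a one-row table with D +/- SE, Z, p, and f +/- SE -- the layout
    admixture scans report per population triplet.
    """
    sums = pattern_sums(polarize(freqs), block_bp, n3=n3)
    d = block_jackknife(sums, "D")
    f = block_jackknife(sums, "f", f_mode)
    return pd.DataFrame(
        [
            dict(
                D=d.value, D_se=d.se, Z=d.z, p_value=d.p_value,
                f=f.value, f_se=f.se, n_blocks=d.n_blocks,
            )
        ]
    )


def population_frequencies(
    haps: dict[str, np.ndarray], scaffolds: np.ndarray, positions: np.ndarray
) -> pd.DataFrame:
    """Derived-frequency table from haplotype matrices keyed p1/p2/p3/po.

    Each matrix is haplotypes x sites with -1 missing; frequencies are
    computed over non-missing haplotypes and nan when a population is
    entirely missing at a site.
    """
    out = {"chrom": scaffolds, "pos": positions}
    for key, H in haps.items():
        called = H != -1
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, H, 0).sum(axis=0) / n
        p = np.where(n > 0, p, np.nan)
        out[key] = p
    return pd.DataFrame(out)
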