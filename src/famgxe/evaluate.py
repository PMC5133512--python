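"""Replicate-level evaluation: TPP/FPP summaries and analytic power.

TPP (true-positive proportion) is the fraction of converged replicate tests
at a causal SNP with p below the nominal level; FPP pools null SNP x
replicate tests into MAF bins after excluding a window around the simulated
effect loci.  The analytic power calculator replaces an external program
with the standard noncentral chi-square form.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, ncx2
from statsmodels.stats.proportion import proportion_confint

from .errors import EvaluationError

DEFAULT_MAF_BINS = (0.001, 0.01, 0.05, 0.10, 0.20, 0.50)


@dataclass
class EvalSummary:
    stratum: str
    n_replicates_converged: int
    n_significant: int
    proportion: float
    ci95: tuple[float, float]


def _wilson(k: int, n: int, method: str = "wilson") -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return float(lo), float(hi)


def _pcol(test: str) -> str:
    if test not in ("1df", "2df"):
        raise EvaluationError("test must be '1df' or '2df'")
    return f"p_{test}"


def tpp(
    results: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "1df",
    ci_method: str = "wilson",
) -> EvalSummary:
    """Proportion of converged replicates significant at ``alpha``.

    ``results`` should already be restricted to one causal SNP and one
    approach (e.g. via boolean indexing on the scan table).
    """
    col = _pcol(test)
    conv = results[results["converged"].astype(bool)]
    n = len(conv)
    if n == 0:
        raise EvaluationError("no converged replicates")
    k = int((conv[col] < alpha).sum())
    label = "/".join(sorted(results["snp"].astype(str).unique()))
    return EvalSummary(label, n, k, k / n, _wilson(k, n, ci_method))


def fpp(
    results: pd.DataFrame,
    causal_loci: list[tuple[str, int]],
    window_bp: int = 500_000,
    maf_bins=DEFAULT_MAF_BINS,
    alpha: float = 0.05,
    test: str = "1df",
    mode: str = "pooled",
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """False-positive proportion per MAF bin, per approach.

    Every SNP within the closed window ``[pos - window_bp, pos + window_bp]``
    on a causal chromosome is excluded (the default 500 kb window around a
    causal SNP at chr7:99,457,518 excludes chr7:98,957,518-99,957,518
    inclusive).  ``mode='pooled'`` pools SNP x replicate tests within a bin;
    ``mode='per_replicate'`` averages per-replicate proportions.
    """
    col = _pcol(test)
    keep = np.ones(len(results), dtype=bool)
    for chrom, pos in causal_loci:
        keep &= ~(
            (results["chrom"].astype(str) == str(chrom))
            & (results["pos"] - pos).abs().le(window_bp)
        )
    df = results[keep & results["converged"].astype(bool)].copy()
    edges = list(maf_bins)
    df["maf_bin"] = pd.cut(df["maf"], edges, right=True)
    out = []
    bins = pd.IntervalIndex.from_breaks(edges)
    for approach, adf in df.groupby("approach", sort=True):
        for b in bins:
            bdf = adf[adf["maf_bin"] == b]
            n = len(bdf)
            if n == 0:
                out.append({"approach": approach, "test": test, "maf_bin": str(b),
                            "n": 0, "k": 0, "proportion": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan})
                continue
            if mode == "pooled":
                k = int((bdf[col] < alpha).sum())
                prop = k / n
                lo, hi = _wilson(k, n, ci_method)
            else:
                per = bdf.groupby("replicate")[col].apply(lambda p: (p < alpha).mean())
                k = int((bdf[col] < alpha).sum())
                prop = float(per.mean())
                lo, hi = _wilson(k, n, ci_method)
            out.append({"approach": approach, "test": test, "maf_bin": str(b),
                        "n": n, "k": k, "proportion": prop,
                        "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(out)


def convergence_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Converged counts per approach (and per chromosome)."""
    if len(results) == 0:
        return pd.DataFrame(columns=["approach", "chrom", "n_tests", "n_converged"])
    g = results.groupby(["approach", "chrom"], sort=True).agg(
        n_tests=("converged", "size"), n_converged=("converged", "sum")
    ).reset_index()
    total = results.groupby("approach", sort=True).agg(
        n_tests=("converged", "size"), n_converged=("converged", "sum")
    ).reset_index()
    total.insert(1, "chrom", "all")
    return pd.concat([g, total], ignore_index=True)


@dataclass
class PowerSpec:
    """Inputs to the analytic power calculation.

    ``df=1``: interaction power for a binary exposure with prevalence
    ``exposure_prevalence`` under gene-environment independence and additive
    coding.  ``df=2``: joint main-effect testing against chi-square(2).
    """

    maf: float
    exposure_prevalence: float
    beta: float               # mm Hg
    sigma2_resid: float       # mm Hg^2
    n_eff: int
    alpha: float = 0.05
    df: int = 2

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise EvaluationError("maf must be in (0, 0.5]")
        if not 0.0 <= self.exposure_prevalence <= 1.0:
            raise EvaluationError("exposure_prevalence must be in [0, 1]")
        if self.sigma2_resid <= 0 or self.n_eff < 1 or self.df not in (1, 2):
            raise EvaluationError("invalid power spec")


def analytic_power(spec: PowerSpec) -> float:
    """Noncentral chi-square power at the nominal level."""
    p, q = spec.maf, spec.exposure_prevalence
    var_g = 2.0 * p * (1.0 - p)
    if spec.df == 1:
        lam = spec.n_eff * spec.beta**2 * var_g * q * (1.0 - q) / spec.sigma2_resid
    else:
        lam = spec.n_eff * spec.beta**2 * var_g / spec.sigma2_resid
    crit = chi2.ppf(1.0 - spec.alpha, spec.df)
    return float(ncx2.sf(crit, spec.df, lam))


def effective_sample_size(n_total: int, factor: float = 0.8) -> int:
    """Effective n approximating the information in related samples."""
    if not 0.0 < factor <= 1.0:
        raise EvaluationError("factor must be in (0, 1]")
    if n_total < 1:
        raise EvaluationError("n_total must be >= 1")
    return int(round(n_total * factor))
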