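"""The two gene-medication interaction approaches and the scan driver.

Interaction model: one mixed model per SNP with SNP, medication and
SNP x medication terms; Wald tests give the 1-df interaction p-value and
the 2-df joint p-value of SNP main and interaction effects.

Med-diff approach: the SNP main effect is fit separately within medication
strata; the stratum difference is tested with a normal Z whose variance is
corrected for the cross-strata Spearman correlation of effect estimates,
and the 2-df joint test sums the two squared stratum Z scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, spearmanr

from .errors import DesignError, FamGxEError
from .lmm import GLSContext, LMMFit, LMMOptions, VarianceComponents, fit_lmm
from .simulate import GenotypePanel, ReplicateDataset
from .relatedness import numerator_relationship_matrix

INTERACTION_MODEL = "interaction_model"
MED_DIFF = "med_diff"


@dataclass
class GxETestResult:
    snp: str
    approach: str
    converged: bool
    reason: str | None = None
    beta_effect: float | None = None       # beta_Int or beta_Diff, mm Hg
    se_effect: float | None = None
    beta_snp_main: float | None = None     # interaction model
    beta_snp_med: float | None = None      # med-diff strata
    beta_snp_unmed: float | None = None
    se_snp_med: float | None = None
    se_snp_unmed: float | None = None
    beta_med: float | None = None          # medication main effect (Model 1)
    p_1df: float | None = None
    p_2df: float | None = None
    maf: float | None = None
    mac: int | None = None
    r_spearman: float | None = None


@dataclass
class StrataCorrelation:
    """Spearman correlation of stratified SNP-effect estimates."""

    r: float
    n_snps_used: int
    scope: str = "per_chromosome"

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise FamGxEError("|r| must be <= 1")


def mac_filter(panel: GenotypePanel, rows=None, threshold: int = 2) -> np.ndarray:
    """Boolean SNP mask: minor-allele count among ``rows`` >= threshold.

    Recomputed per analysis subset, so stratified fits re-filter within
    stratum.  Dosages are rounded to nearest before counting.
    """
    if threshold < 0:
        raise FamGxEError("threshold must be >= 0")
    d = panel.dosages if rows is None else panel.dosages[np.asarray(rows)]
    counts = np.rint(d).sum(axis=0)
    mac = np.minimum(counts, 2 * d.shape[0] - counts)
    return mac >= threshold


def interaction_test(
    fit: LMMFit,
    snp_name: str = "snp",
    int_name: str = "snp_x_med",
    snp: str = "",
) -> GxETestResult:
    """Wald 1-df (interaction) and 2-df (SNP main + interaction) tests."""
    if not fit.converged:
        return GxETestResult(snp, INTERACTION_MODEL, False, fit.reason or "fit not converged")
    b, C = fit.wald_block([snp_name, int_name])
    var_int = C[1, 1]
    if var_int <= 0 or not np.all(np.isfinite(C)):
        return GxETestResult(snp, INTERACTION_MODEL, False, "singular covariance")
    x1 = b[1] ** 2 / var_int
    try:
        x2 = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError:
        return GxETestResult(snp, INTERACTION_MODEL, False, "singular covariance")
    return GxETestResult(
        snp, INTERACTION_MODEL, True, None,
        beta_effect=float(b[1]), se_effect=float(np.sqrt(var_int)),
        beta_snp_main=float(b[0]),
        beta_med=float(fit.beta["med"]) if "med" in fit.beta.index else None,
        p_1df=float(chi2.sf(x1, 1)), p_2df=float(chi2.sf(x2, 2)),
    )


def med_diff_test(
    fit_med: LMMFit | None,
    fit_unmed: LMMFit | None,
    r: StrataCorrelation,
    snp_name: str = "snp",
    snp: str = "",
) -> GxETestResult:
    """Correlation-corrected difference test and 2-df joint stratum test.

    Z = (b1 - b0) / sqrt(se1^2 + se0^2 - 2 r se1 se0) ~ N(0,1) under no
    difference; X_2df = z1^2 + z0^2 ~ chi-square(2) under no effect in
    either stratum.
    """
    for f, lab in ((fit_med, "medicated"), (fit_unmed, "unmedicated")):
        if f is None or not f.converged:
            reason = f.reason if f is not None else "missing stratum fit"
            return GxETestResult(snp, MED_DIFF, False, f"{lab} stratum: {reason}")
    b1, se1 = float(fit_med.beta[snp_name]), float(np.sqrt(fit_med.covariance.loc[snp_name, snp_name]))
    b0, se0 = float(fit_unmed.beta[snp_name]), float(np.sqrt(fit_unmed.covariance.loc[snp_name, snp_name]))
    var_diff = se1**2 + se0**2 - 2.0 * r.r * se1 * se0
    if var_diff <= 0:
        return GxETestResult(snp, MED_DIFF, False, "non-positive difference variance")
    z = (b1 - b0) / np.sqrt(var_diff)
    x2 = (b1 / se1) ** 2 + (b0 / se0) ** 2
    return GxETestResult(
        snp, MED_DIFF, True, None,
        beta_effect=b1 - b0, se_effect=float(np.sqrt(var_diff)),
        beta_snp_med=b1, beta_snp_unmed=b0, se_snp_med=se1, se_snp_unmed=se0,
        p_1df=float(2.0 * norm.sf(abs(z))), p_2df=float(chi2.sf(x2, 2)),
        r_spearman=r.r,
    )


def spearman_strata_correlation(
    beta_med, beta_unmed, scope: str = "per_chromosome"
) -> StrataCorrelation:
    """Spearman rank correlation of stratified effect estimates (ties by
    average rank)."""
    b1 = np.asarray(beta_med, dtype=float)
    b0 = np.asarray(beta_unmed, dtype=float)
    ok = np.isfinite(b1) & np.isfinite(b0)
    if ok.sum() < 2:
        raise FamGxEError("need >= 2 SNPs with estimates in both strata")
    r = spearmanr(b1[ok], b0[ok]).statistic
    if np.isnan(r):  # constant vector
        r = 0.0
    return StrataCorrelation(float(r), int(ok.sum()), scope)


# ---------------------------------------------------------------------------
# scan driver


@dataclass
class ScanOptions:
    residual_model: str = "heterogeneous"   # Model-1 residuals; "homogeneous" to pool
    vc_mode: str = "scan"                   # "scan": components from null fit; "exact": per-SNP REML
    mac_threshold: int = 2
    spearman_scope: str = "per_chromosome"  # or "genome_wide"
    lmm: LMMOptions = field(default_factory=LMMOptions)


def _design(phen: pd.DataFrame, covariates: list[str], extra: dict[str, np.ndarray]) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(phen))}
    for c in covariates:
        if c == "sex":
            cols["sex"] = (phen["sex"] == "female").astype(float).to_numpy()
        else:
            cols[c] = phen[c].to_numpy(dtype=float)
    cols.update(extra)
    return pd.DataFrame(cols, index=phen.index)


def default_covariates(phen: pd.DataFrame) -> list[str]:
    pcs = sorted(
        (c for c in phen.columns if c.startswith("pc") and c[2:].isdigit()),
        key=lambda c: int(c[2:]),
    )
    return ["age", "sex", *pcs]


def stratified_fits(
    dataset: ReplicateDataset,
    snp: str,
    covariates: list[str] | None = None,
    options: ScanOptions | None = None,
) -> tuple[LMMFit | None, LMMFit | None]:
    """Exact per-stratum mixed-model fits of the SNP main effect.

    Returns (medicated fit, unmedicated fit); a stratum that is empty or has
    in-stratum MAC below threshold yields a non-converged placeholder with
    reason "small stratified-sample size"."""
    options = options or ScanOptions(vc_mode="exact")
    covariates = covariates or default_covariates(dataset.phenotypes)
    R = dataset.relationship or numerator_relationship_matrix(dataset.pedigree)
    phen = dataset.phenotypes
    out = []
    for med_value in (1, 0):
        rows = np.flatnonzero(phen["med"].to_numpy() == med_value)
        reason = None
        if rows.size == 0:
            reason = "small stratified-sample size"
        elif not mac_filter(dataset.genotypes, rows, options.mac_threshold)[
            dataset.genotypes.snp_meta.index.get_loc(snp)
        ]:
            reason = "small stratified-sample size"
        if reason:
            out.append(
                LMMFit(pd.Series(dtype=float), pd.DataFrame(),
                       VarianceComponents(0.0, {"all": 0.0}),
                       -np.inf, -np.inf, False, reason, int(rows.size), 0, [])
            )
            continue
        g = dataset.genotypes.column(snp)[rows]
        X = _design(phen.iloc[rows], covariates, {"snp": g})
        try:
            fit = fit_lmm(
                phen["sbp_t3"].to_numpy()[rows], X, R.subset(rows),
                residual_groups=None, options=options.lmm,
            )
        except DesignError as exc:
            fit = LMMFit(pd.Series(dtype=float), pd.DataFrame(),
                         VarianceComponents(0.0, {"all": 0.0}),
                         -np.inf, -np.inf, False, f"degenerate design: {exc}",
                         int(rows.size), 0, [])
        out.append(fit)
    return out[0], out[1]


def _null_fit(phen, covariates, R, residual_groups, options):
    X = _design(phen, covariates, {"med": phen["med"].to_numpy(dtype=float)})
    return fit_lmm(phen["sbp_t3"].to_numpy(), X, R,
                   residual_groups=residual_groups, options=options.lmm)


def _interaction_scan(dataset, snps, covariates, options) -> list[GxETestResult]:
    phen = dataset.phenotypes
    panel = dataset.genotypes
    R = dataset.relationship or numerator_relationship_matrix(dataset.pedigree)
    med = phen["med"].to_numpy(dtype=float)
    groups = med.astype(int).astype(str) if options.residual_model == "heterogeneous" else None
    results = []
    if options.vc_mode == "scan":
        null = _null_fit(phen, covariates, R, groups, options)
        if not null.converged:
            return [GxETestResult(s, INTERACTION_MODEL, False, "null model not converged")
                    for s in snps]
        ctx = GLSContext(R, null.vc, groups)
        Xcov = _design(phen, covariates, {"med": med})
        names = list(Xcov.columns) + ["snp", "snp_x_med"]
        Xw = ctx.whiten(Xcov.to_numpy(dtype=float))
        yw = ctx.whiten(phen["sbp_t3"].to_numpy())
        cols = [panel.snp_meta.index.get_loc(s) for s in snps]
        Gw = ctx.whiten(panel.dosages[:, cols])
        GMw = ctx.whiten(panel.dosages[:, cols] * med[:, None])
        for j, s in enumerate(snps):
            Xs = np.column_stack([Xw, Gw[:, j], GMw[:, j]])
            sol = ctx.gls(Xs, yw, names)
            if sol is None:
                results.append(GxETestResult(
                    s, INTERACTION_MODEL, False,
                    "multicollinearity between the SNP and interaction terms"))
                continue
            beta, cov = sol
            fit = LMMFit(beta, cov, null.vc, null.loglik_reml, null.loglik_ml,
                         True, None, len(phen), 0, names)
            results.append(interaction_test(fit, snp=s))
    else:
        for s in snps:
            g = panel.column(s)
            X = _design(phen, covariates, {"med": med, "snp": g, "snp_x_med": g * med})
            try:
                fit = fit_lmm(phen["sbp_t3"].to_numpy(), X, R,
                              residual_groups=groups, options=options.lmm)
                results.append(interaction_test(fit, snp=s))
            except DesignError:
                results.append(GxETestResult(
                    s, INTERACTION_MODEL, False,
                    "multicollinearity between the SNP and interaction terms"))
    return results


def _med_diff_scan(dataset, snps, covariates, options) -> list[GxETestResult]:
    phen = dataset.phenotypes
    panel = dataset.genotypes
    R = dataset.relationship or numerator_relationship_matrix(dataset.pedigree)
    med = phen["med"].to_numpy()
    estimates: dict[str, dict] = {}
    if options.vc_mode == "scan":
        for label, med_value in (("med", 1), ("unmed", 0)):
            rows = np.flatnonzero(med == med_value)
            if rows.size == 0:
                for s in snps:
                    estimates.setdefault(s, {})[label] = (None, "small stratified-sample size")
                continue
            sub = phen.iloc[rows]
            Rs = R.subset(rows)
            Xcov = _design(sub, covariates, {})
            null = fit_lmm(sub["sbp_t3"].to_numpy(), Xcov, Rs, options=options.lmm)
            ok_mask = mac_filter(panel, rows, options.mac_threshold)
            if not null.converged:
                for s in snps:
                    estimates.setdefault(s, {})[label] = (None, "null model not converged")
                continue
            ctx = GLSContext(Rs, null.vc, None)
            names = list(Xcov.columns) + ["snp"]
            Xw = ctx.whiten(Xcov.to_numpy(dtype=float))
            yw = ctx.whiten(sub["sbp_t3"].to_numpy())
            cols = [panel.snp_meta.index.get_loc(s) for s in snps]
            Gw = ctx.whiten(panel.dosages[np.ix_(rows, cols)])
            for j, s in enumerate(snps):
                if not ok_mask[panel.snp_meta.index.get_loc(s)]:
                    estimates.setdefault(s, {})[label] = (None, "small stratified-sample size")
                    continue
                sol = ctx.gls(np.column_stack([Xw, Gw[:, j]]), yw, names)
                if sol is None:
                    estimates.setdefault(s, {})[label] = (None, "degenerate design")
                    continue
                beta, cov = sol
                fit = LMMFit(beta, cov, null.vc, null.loglik_reml, null.loglik_ml,
                             True, None, rows.size, 0, names)
                estimates.setdefault(s, {})[label] = (fit, None)
    else:
        for s in snps:
            fm, fu = stratified_fits(dataset, s, covariates, options)
            estimates.setdefault(s, {})["med"] = (fm if fm.converged else None,
                                                  None if fm.converged else fm.reason)
            estimates[s]["unmed"] = (fu if fu.converged else None,
                                     None if fu.converged else fu.reason)

    # Spearman r over SNPs with both strata converged, per chromosome
    meta = panel.snp_meta
    chrom_of = {s: meta.loc[s, "chrom"] for s in snps}
    scopes = (
        {s: chrom_of[s] for s in snps}
        if options.spearman_scope == "per_chromosome"
        else {s: "genome" for s in snps}
    )
    r_by_scope: dict[str, StrataCorrelation] = {}
    for scope_key in set(scopes.values()):
        b1, b0 = [], []
        for s in snps:
            if scopes[s] != scope_key:
                continue
            em = estimates[s].get("med", (None, None))[0]
            eu = estimates[s].get("unmed", (None, None))[0]
            if em is not None and eu is not None:
                b1.append(float(em.beta["snp"]))
                b0.append(float(eu.beta["snp"]))
        try:
            r_by_scope[scope_key] = spearman_strata_correlation(
                b1, b0, options.spearman_scope)
        except FamGxEError:
            r_by_scope[scope_key] = StrataCorrelation(0.0, 2, options.spearman_scope)

    results = []
    for s in snps:
        em, rm = estimates[s].get("med", (None, "missing"))
        eu, ru = estimates[s].get("unmed", (None, "missing"))
        r = r_by_scope[scopes[s]]
        if em is None or eu is None:
            reason = rm or ru or "stratum fit failed"
            results.append(GxETestResult(s, MED_DIFF, False, reason, r_spearman=r.r))
        else:
            results.append(med_diff_test(em, eu, r, snp=s))
    return results


def run_scan(
    dataset: ReplicateDataset,
    approach: str = "both",
    snp_set: list[str] | None = None,
    covariates: list[str] | None = None,
    options: ScanOptions | None = None,
) -> pd.DataFrame:
    """Per-replicate scan producing one row per SNP per approach.

    Applies the MAC filter over the analyzed rows, runs the requested
    approach(es) on passing SNPs, and reports non-passing/non-converged
    SNPs with ``converged=False`` so convergence denominators survive.
    """
    options = options or ScanOptions()
    if approach not in (INTERACTION_MODEL, MED_DIFF, "both"):
        raise FamGxEError(f"unknown approach {approach!r}")
    phen = dataset.phenotypes
    if "med" not in phen.columns:
        raise FamGxEError("phenotypes lack a 'med' column; medication status required")
    covariates = covariates or default_covariates(phen)
    panel = dataset.genotypes
    meta = panel.snp_meta
    all_snps = list(meta.index) if snp_set is None else list(snp_set)
    missing = [s for s in all_snps if s not in meta.index]
    if missing:
        raise FamGxEError(f"SNPs not in panel: {missing}")
    ok = mac_filter(panel, None, options.mac_threshold)
    passing = [s for s in all_snps if ok[meta.index.get_loc(s)]]
    excluded = [s for s in all_snps if s not in passing]

    approaches = [INTERACTION_MODEL, MED_DIFF] if approach == "both" else [approach]
    rows = []
    for app in approaches:
        if app == INTERACTION_MODEL:
            res = _interaction_scan(dataset, passing, covariates, options)
        else:
            res = _med_diff_scan(dataset, passing, covariates, options)
        res += [GxETestResult(s, app, False, "MAC below threshold") for s in excluded]
        for t in res:
            rows.append({
                "replicate": dataset.replicate_index,
                "chrom": meta.loc[t.snp, "chrom"],
                "pos": int(meta.loc[t.snp, "pos"]),
                "snp": t.snp,
                "maf": float(meta.loc[t.snp, "maf"]),
                "mac": int(meta.loc[t.snp, "mac"]),
                "approach": t.approach,
                "beta_effect": t.beta_effect,
                "se_effect": t.se_effect,
                "beta_snp_main": t.beta_snp_main,
                "beta_snp_med": t.beta_snp_med,
                "beta_snp_unmed": t.beta_snp_unmed,
                "se_snp_med": t.se_snp_med,
                "se_snp_unmed": t.se_snp_unmed,
                "beta_med": t.beta_med,
                "p_1df": t.p_1df,
                "p_2df": t.p_2df,
                "converged": t.converged,
                "reason": t.reason,
                "r_spearman": t.r_spearman,
                "vc_mode": options.vc_mode,
            })
    return pd.DataFrame(rows)
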