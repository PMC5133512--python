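import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest, spearmanr

from famgxe import (
    CausalSnp,
    FamGxEError,
    FamilyTemplate,
    GenotypePanel,
    LMMFit,
    ScanOptions,
    SimConfig,
    SnpSpec,
    StrataCorrelation,
    VarianceComponents,
    generate_replicates,
    interaction_test,
    mac_filter,
    med_diff_test,
    run_scan,
    spearman_strata_correlation,
    stratified_fits,
)


def _panel_from_dosages(d):
    d = np.asarray(d, dtype=float)
    m = d.shape[1]
    meta = GenotypePanel.realized_meta(
        d, ["1"] * m, list(range(1, m + 1)),
        pd.Index([f"s{j}" for j in range(m)], name="snp"),
    )
    return GenotypePanel(d, meta, [f"i{k}" for k in range(d.shape[0])])


def _fake_fit(names, beta, cov):
    beta = pd.Series(beta, index=names)
    cov = pd.DataFrame(cov, index=names, columns=names)
    return LMMFit(beta, cov, VarianceComponents(1.0, {"all": 1.0}),
                  0.0, 0.0, True, None, 100, 1, list(names))


# ---------------------------------------------------------------------------
# MAC filter


def test_mac_filter_boundary():
    """MAC 1 excluded, MAC exactly 2 retained, monomorphic excluded."""
    d = np.zeros((50, 3))
    d[0, 0] = 1            # MAC 1
    d[0, 1], d[1, 1] = 1, 1  # MAC 2
    panel = _panel_from_dosages(d)
    np.testing.assert_array_equal(mac_filter(panel), [False, True, False])


def test_mac_filter_recomputed_within_subset():
    d = np.zeros((50, 1))
    d[0, 0], d[1, 0] = 1, 1
    panel = _panel_from_dosages(d)
    assert mac_filter(panel, rows=np.arange(50))[0]
    assert not mac_filter(panel, rows=np.arange(2, 50))[0]


def test_mac_filter_counts_minor_allele():
    d = np.full((50, 1), 2.0)
    d[0, 0] = 1.0          # minor allele is the reference: MAC 1
    panel = _panel_from_dosages(d)
    assert not mac_filter(panel)[0]


# ---------------------------------------------------------------------------
# interaction-model Wald tests


def test_zero_interaction_gives_p_one():
    fit = _fake_fit(["snp", "snp_x_med"], [1.0, 0.0], np.eye(2))
    res = interaction_test(fit)
    assert res.p_1df == 1.0
    assert res.beta_effect == 0.0


def test_identity_covariance_closed_form():
    """beta_SNP=2, beta_Int=1, C=I: X_2df = 5 so p = exp(-5/2) ~ 0.0821."""
    fit = _fake_fit(["snp", "snp_x_med"], [2.0, 1.0], np.eye(2))
    res = interaction_test(fit)
    assert res.p_2df == pytest.approx(np.exp(-2.5), rel=1e-10)
    from scipy.stats import norm
    assert res.p_1df == pytest.approx(2 * norm.sf(1.0), rel=1e-10)  # chi2(1) at 1


def test_correlated_covariance_matches_bruteforce_inverse():
    b = np.array([1.5, -0.8])
    se = np.array([0.7, 0.4])
    C = np.array([[se[0] ** 2, 0.5 * se[0] * se[1]],
                  [0.5 * se[0] * se[1], se[1] ** 2]])
    fit = _fake_fit(["snp", "snp_x_med"], b, C)
    res = interaction_test(fit)
    # explicit 2x2 inverse
    det = C[0, 0] * C[1, 1] - C[0, 1] ** 2
    Cinv = np.array([[C[1, 1], -C[0, 1]], [-C[0, 1], C[0, 0]]]) / det
    x2 = float(b @ Cinv @ b)
    assert res.p_2df == pytest.approx(np.exp(-x2 / 2), rel=1e-10)


def test_nonconverged_fit_propagates():
    fit = _fake_fit(["snp", "snp_x_med"], [1.0, 1.0], np.eye(2))
    fit.converged = False
    fit.reason = "why"
    res = interaction_test(fit)
    assert not res.converged and res.p_1df is None


# ---------------------------------------------------------------------------
# med-diff tests


def test_equal_strata_effects_give_z_zero():
    f1 = _fake_fit(["snp"], [2.0], [[1.0]])
    f0 = _fake_fit(["snp"], [2.0], [[4.0]])
    res = med_diff_test(f1, f0, StrataCorrelation(0.0, 10))
    assert res.p_1df == 1.0
    assert res.beta_effect == 0.0


def test_difference_test_arithmetic_oracle():
    """b1=4, b0=0, se1=2, se0=1, r=0: Z = 4/sqrt(5), two-sided p ~ 0.0736."""
    f1 = _fake_fit(["snp"], [4.0], [[4.0]])
    f0 = _fake_fit(["snp"], [0.0], [[1.0]])
    res = med_diff_test(f1, f0, StrataCorrelation(0.0, 10))
    assert res.beta_effect == pytest.approx(4.0)
    assert res.se_effect == pytest.approx(np.sqrt(5.0))
    assert res.p_1df == pytest.approx(0.0736, abs=2e-4)
    # z1=2, z0=0: X_2df = 4
    assert res.p_2df == pytest.approx(np.exp(-2.0), rel=1e-10)


def test_joint_test_chi2_survival():
    """z1=2, z0=1: X_2df = 5, p = exp(-5/2)."""
    f1 = _fake_fit(["snp"], [2.0], [[1.0]])
    f0 = _fake_fit(["snp"], [1.0], [[1.0]])
    res = med_diff_test(f1, f0, StrataCorrelation(0.0, 10))
    assert res.p_2df == pytest.approx(np.exp(-2.5), rel=1e-10)


def test_joint_test_invariant_to_stratum_swap():
    f1 = _fake_fit(["snp"], [2.0], [[1.5]])
    f0 = _fake_fit(["snp"], [-1.0], [[0.5]])
    r = StrataCorrelation(-0.1, 10)
    a = med_diff_test(f1, f0, r)
    b = med_diff_test(f0, f1, r)
    assert a.p_2df == pytest.approx(b.p_2df, rel=1e-12)
    assert a.p_1df == pytest.approx(b.p_1df, rel=1e-12)


def test_degenerate_difference_variance_guarded():
    f1 = _fake_fit(["snp"], [1.0], [[1.0]])
    f0 = _fake_fit(["snp"], [0.0], [[1.0]])
    res = med_diff_test(f1, f0, StrataCorrelation(1.0, 10))
    assert not res.converged


def test_nonconverged_stratum_propagates():
    f1 = _fake_fit(["snp"], [1.0], [[1.0]])
    f0 = _fake_fit(["snp"], [0.0], [[1.0]])
    f0.converged, f0.reason = False, "small stratified-sample size"
    res = med_diff_test(f1, f0, StrataCorrelation(0.0, 10))
    assert not res.converged
    assert "small stratified-sample size" in res.reason


@given(
    b1=st.floats(-5, 5), b0=st.floats(-5, 5),
    se1=st.floats(0.1, 3), se0=st.floats(0.1, 3),
    r=st.floats(-0.5, 0.5),
)
@settings(max_examples=60, deadline=None)
def test_pvalues_always_in_unit_interval(b1, b0, se1, se0, r):
    f1 = _fake_fit(["snp"], [b1], [[se1 ** 2]])
    f0 = _fake_fit(["snp"], [b0], [[se0 ** 2]])
    res = med_diff_test(f1, f0, StrataCorrelation(r, 10))
    assert res.converged
    assert 0.0 <= res.p_1df <= 1.0
    assert 0.0 <= res.p_2df <= 1.0


# ---------------------------------------------------------------------------
# Spearman correlation


def test_spearman_identical_and_reversed():
    x = [1.0, 3.0, 2.0, 5.0]
    assert spearman_strata_correlation(x, x).r == pytest.approx(1.0)
    assert spearman_strata_correlation(x, [-v for v in x]).r == pytest.approx(-1.0)


def test_spearman_ties_match_average_rank_formula():
    """Hand-ranked oracle on 6 values with ties (average ranks), compared as
    the Pearson correlation of the hand-written rank vectors."""
    x = [1.0, 2.0, 2.0, 3.0, 3.0, 4.0]
    y = [10.0, 30.0, 20.0, 20.0, 40.0, 40.0]
    rx = np.array([1.0, 2.5, 2.5, 4.5, 4.5, 6.0])
    ry = np.array([1.0, 4.0, 2.5, 2.5, 5.5, 5.5])
    expected = np.corrcoef(rx, ry)[0, 1]
    assert spearman_strata_correlation(x, y).r == pytest.approx(expected, rel=1e-12)


def test_spearman_needs_two_points():
    with pytest.raises(FamGxEError):
        spearman_strata_correlation([1.0], [2.0])


# ---------------------------------------------------------------------------
# stratified fits and scan driver


def _small_scan_config(**kw):
    base = dict(
        n_families=6,
        family_template=FamilyTemplate(3, (2, 3)),
        null_snps=[SnpSpec(f"chr1:{j}", "1", j, 0.3) for j in (100, 200, 300)],
        n_replicates=1,
        seed=21,
        attach_pcs=False,
    )
    base.update(kw)
    return SimConfig(**base)


def test_stratified_fit_monomorphic_stratum_nonconverged():
    cfg = _small_scan_config()
    ds = next(generate_replicates(cfg))
    # force a SNP monomorphic among the medicated
    med = ds.phenotypes["med"].to_numpy()
    d = ds.genotypes.dosages.copy()
    d[med == 1, 0] = 0.0
    ds.genotypes.dosages = d
    fm, fu = stratified_fits(ds, "chr1:100")
    assert not fm.converged
    assert "stratified" in fm.reason
    assert fu.converged


def test_stratified_fits_recover_stratum_slopes():
    """Simulated stratum-specific SNP effects (4 vs 0) are recovered."""
    causal = CausalSnp("c", "1", 50, 0.4, beta_snp=0.0, beta_int=4.0)
    cfg = _small_scan_config(
        causal_snps=[causal], n_replicates=30, seed=33,
        sigma2_additive=10.0, sigma2_resid_unmed=20.0, sigma2_resid_med=20.0,
    )
    b1s, b0s = [], []
    for ds in generate_replicates(cfg):
        fm, fu = stratified_fits(ds, "c")
        if fm.converged and fu.converged:
            b1s.append(float(fm.beta["snp"]))
            b0s.append(float(fu.beta["snp"]))
    b1s, b0s = np.array(b1s), np.array(b0s)
    assert abs(b1s.mean() - 4.0) < 3 * b1s.std(ddof=1) / np.sqrt(len(b1s)) + 0.2
    assert abs(b0s.mean() - 0.0) < 3 * b0s.std(ddof=1) / np.sqrt(len(b0s)) + 0.2


def test_scan_covers_both_approaches_identically():
    cfg = _small_scan_config()
    ds = next(generate_replicates(cfg))
    res = run_scan(ds, approach="both")
    by_app = res.groupby("approach")["snp"].apply(set)
    assert by_app["interaction_model"] == by_app["med_diff"]
    assert set(res["vc_mode"]) == {"scan"}


def test_scan_emits_nonconverged_rows_for_filtered_snps():
    cfg = _small_scan_config()
    ds = next(generate_replicates(cfg))
    d = ds.genotypes.dosages.copy()
    d[:, 1] = 0.0
    d[0, 1] = 1.0  # MAC 1
    ds.genotypes.dosages = d
    res = run_scan(ds, approach="interaction_model")
    row = res[res["snp"] == "chr1:200"].iloc[0]
    assert not row["converged"]
    assert "MAC" in row["reason"]
    assert len(res) == 3


def test_scan_rejects_missing_medication():
    cfg = _small_scan_config()
    ds = next(generate_replicates(cfg))
    ds.phenotypes = ds.phenotypes.drop(columns=["med"])
    with pytest.raises(FamGxEError, match="med"):
        run_scan(ds)


def test_null_pvalues_uniform():
    """1DF p-values from a null scan are ~Uniform(0,1) (KS at alpha=0.01)."""
    cfg = SimConfig(
        n_families=8, family_template=FamilyTemplate(3, (2, 3)),
        null_snps=[SnpSpec(f"chr1:{1000 + j}", "1", 1000 + j, maf)
                   for j, maf in enumerate(np.linspace(0.1, 0.5, 120))],
        n_replicates=4, seed=77, attach_pcs=False,
    )
    ps = []
    for ds in generate_replicates(cfg):
        res = run_scan(ds, approach="interaction_model")
        ps.extend(res[res["converged"]]["p_1df"].tolist())
    assert kstest(ps, "uniform").pvalue > 0.01


def test_interaction_and_med_diff_agree_for_common_snps_unrelated():
    """In the theoretical-equivalence regime (unrelated individuals,
    homoscedastic residuals, common MAF) the two 1DF p-values agree with
    rank correlation > 0.95."""
    cfg = SimConfig(
        n_families=300, family_template=FamilyTemplate(1, ()),
        null_snps=[SnpSpec(f"chr1:{1000 + j}", "1", 1000 + j, maf)
                   for j, maf in enumerate(np.linspace(0.2, 0.5, 60))],
        sigma2_additive=0.0, sigma2_resid_unmed=120.0, sigma2_resid_med=120.0,
        n_replicates=1, seed=13, attach_pcs=False,
    )
    ds = next(generate_replicates(cfg))
    res = run_scan(ds, approach="both",
                   options=ScanOptions(residual_model="homogeneous"))
    piv = res.pivot_table(index="snp", columns="approach", values="p_1df")
    rho = spearmanr(piv["interaction_model"], piv["med_diff"]).statistic
    assert rho > 0.95


def test_causal_snp_flagged_more_than_null():
    """A CYP3A43-style interaction SNP (MAF ~5%) is significant more often
    than null SNPs across replicates, for both approaches."""
    causal = CausalSnp("chr7:99457605", "7", 99457605, 0.054, 0.0, 6.2)
    cfg = SimConfig(
        n_families=20,
        null_snps=[SnpSpec(f"chr1:{1000 + j}", "1", 1000 + j, 0.054)
                   for j in range(3)],
        causal_snps=[causal], n_replicates=8, seed=5, attach_pcs=False,
    )
    hits = {"interaction_model": [0, 0], "med_diff": [0, 0]}
    for ds in generate_replicates(cfg):
        res = run_scan(ds, approach="both")
        conv = res[res["converged"]]
        for app, adf in conv.groupby("approach"):
            hits[app][0] += int((adf.loc[adf["snp"] == "chr7:99457605", "p_1df"] < 0.05).sum())
            hits[app][1] += int((adf.loc[adf["snp"] != "chr7:99457605", "p_1df"] < 0.05).sum() > 0)
    for app, (causal_hits, _) in hits.items():
        assert causal_hits >= 3, app  # power well above the 5% null rate
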