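"""Biometric builders: expected covariances, identification rules, nesting
relations between families, and standardised decompositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinstab.biometric import (
    FAMILIES,
    CholeskyEstimates,
    build_cholesky,
    build_common_pathway,
    build_correlated_factors,
    build_univariate,
    component_correlations,
    compose_twin_cov,
    moment_component_estimates,
    standardize,
    univariate_expected_cov,
)
from twinstab.models import FitResult, fit
from twinstab.fiml import PatternStats, neg2_loglik
from twinstab.recovery import univariate_truth
from twinstab.simulate import simulate
from twinstab.data import sqrt_transform


# -- expected covariance algebra ---------------------------------------------


def test_univariate_ae_expected_cov():
    s_mz, s_dz, mu = univariate_expected_cov("AE", means=1.5, a2=0.39, e2=0.61)
    np.testing.assert_allclose(s_mz, [[1.0, 0.39], [0.39, 1.0]], atol=1e-12)
    np.testing.assert_allclose(s_dz, [[1.0, 0.195], [0.195, 1.0]], atol=1e-12)
    np.testing.assert_allclose(mu, [1.5, 1.5])


def test_univariate_ade_expected_cov():
    """A 0.40 + D 0.15 + E 0.45: MZ cross 0.55, DZ cross 0.5*0.40+0.25*0.15."""
    s_mz, s_dz, _ = univariate_expected_cov("ADE", a2=0.40, d2=0.15, e2=0.45)
    assert s_mz[0, 1] == pytest.approx(0.55)
    assert s_dz[0, 1] == pytest.approx(0.2375)
    assert s_mz[0, 0] == pytest.approx(1.0)


def test_ace_shared_environment_equal_cross_twin_weight():
    s_mz, s_dz, _ = univariate_expected_cov("ACE", a2=0.0, c2=0.3, e2=0.7)
    assert s_mz[0, 1] == s_dz[0, 1] == pytest.approx(0.3)


def test_c_and_d_jointly_rejected():
    with pytest.raises(ValueError, match="C and D"):
        compose_twin_cov({"A": np.eye(1), "C": np.eye(1), "D": np.eye(1),
                          "E": np.eye(1)})


def test_e_component_required():
    with pytest.raises(ValueError, match="E is required"):
        compose_twin_cov({"A": np.eye(1)})


def test_component_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        compose_twin_cov({"A": np.eye(2), "E": np.eye(3)})


def test_unknown_family_rejected():
    with pytest.raises(ValueError, match="unknown family"):
        build_univariate("AXE")
    assert set(FAMILIES) == {"ACE", "ADE", "AE", "CE", "E"}


def test_component_correlations_identity_for_diagonal():
    assert np.allclose(component_correlations(np.diag([2.0, 3.0])), np.eye(2))
    m = np.array([[1.0, 0.9], [0.9, 1.0]])
    np.testing.assert_allclose(component_correlations(2.5 * m), m, atol=1e-12)


# -- moment starts ------------------------------------------------------------


def test_moment_estimates_near_truth():
    cfg = univariate_truth(seed=5, n_mz=30000, n_dz=30000)
    cfg.skew = False
    cfg.missing_rate = 0.0
    data, _ = simulate(cfg)
    est = moment_component_estimates(data.group_arrays(), 1, ("A", "E"))
    assert est["A"][0, 0] == pytest.approx(0.39, abs=0.02)
    assert est["E"][0, 0] == pytest.approx(0.61, abs=0.02)


# -- nesting ladders ----------------------------------------------------------


def test_univariate_family_nesting(small_univariate_groups):
    """E is nested in AE is nested in ACE: the maximised -2LL can only
    improve down the ladder, and ACE cannot beat the saturated bound."""
    groups, _ = small_univariate_groups
    fits = {
        f: fit(build_univariate(f, data=groups), groups, n_starts=2,
               standard_errors=False)
        for f in ("E", "AE", "ACE")
    }
    assert fits["E"].minus2ll >= fits["AE"].minus2ll - 1e-6
    assert fits["AE"].minus2ll >= fits["ACE"].minus2ll - 1e-6
    assert fits["E"].k < fits["AE"].k < fits["ACE"].k


def test_common_pathway_nested_in_cholesky(small_cpm_dataset):
    """The common pathway model restricts the Cholesky decomposition, so its
    maximised -2LL is never lower."""
    data, _ = small_cpm_dataset
    groups = sqrt_transform(data).group_arrays()
    chol = fit(build_cholesky(6, data=groups), groups, n_starts=1,
               standard_errors=False)
    cpm = fit(build_common_pathway(6, data=groups), groups, n_starts=1,
              standard_errors=False)
    assert cpm.minus2ll >= chol.minus2ll - 1e-6
    assert cpm.k < chol.k


def test_correlated_factors_equals_bivariate_cholesky(small_bivariate_groups):
    """For two variables the correlated-factor model is a reparameterisation
    of the bivariate Cholesky: identical maximised likelihoods."""
    groups, _ = small_bivariate_groups
    chol = fit(build_cholesky(2, data=groups), groups, n_starts=2,
               standard_errors=False)
    corr = fit(build_correlated_factors(2, data=groups), groups, n_starts=2,
               standard_errors=False)
    assert corr.minus2ll == pytest.approx(chol.minus2ll, abs=1e-4)
    assert corr.k == chol.k


def test_cpm_zero_loadings_equal_diagonal_cholesky():
    """With all latent loadings at zero the common pathway covariance
    reduces to the purely wave-specific (diagonal) structure."""
    spec = build_common_pathway(3)
    # theta = [lambda(3), phi(1), sA(3), sE(3), means(3)]
    theta = np.array([0.0, 0.0, 0.0, 0.5, 0.4, 0.5, 0.6, 0.7, 0.6, 0.5, 0, 0, 0],
                     float)
    (mu_mz, s_mz), (mu_dz, s_dz) = spec.builder(theta)
    a = np.array([0.4, 0.5, 0.6]) ** 2
    e = np.array([0.7, 0.6, 0.5]) ** 2
    within = np.diag(a + e)
    np.testing.assert_allclose(s_mz[:3, :3], within, atol=1e-12)
    np.testing.assert_allclose(s_mz[:3, 3:], np.diag(a), atol=1e-12)
    np.testing.assert_allclose(s_dz[:3, 3:], np.diag(0.5 * a), atol=1e-12)


def test_cpm_requires_three_waves():
    with pytest.raises(ValueError, match="at least 3"):
        build_common_pathway(2)
    with pytest.raises(ValueError, match="at least 2"):
        build_correlated_factors(1)


# -- standardisation ----------------------------------------------------------


def test_cholesky_standardize_arithmetic():
    """Hand-checkable 2-wave decomposition: shares are squared paths over
    the wave's total variance."""
    spec = build_cholesky(2)
    # xA = [[0.6, .], [0.3, 0.4]], xE = [[0.8, .], [0.2, 0.5]]
    theta = np.array([0.6, 0.3, 0.4, 0.8, 0.2, 0.5, 0.0, 0.0])
    res = FitResult(model=spec.name, theta=theta,
                    param_names=spec.param_names, minus2ll=0.0, k=spec.k,
                    n_rows=0, n_values=0, converged=True, meta=spec.meta)
    est = standardize(res)
    assert isinstance(est, CholeskyEstimates)
    v1 = 0.6**2 + 0.8**2
    v2 = 0.3**2 + 0.4**2 + 0.2**2 + 0.5**2
    assert est.shares["A"][0, 0] == pytest.approx(0.36 / v1)
    assert est.shares["A"][1, 0] == pytest.approx(0.09 / v2)
    assert est.total_shares["A"][1] == pytest.approx((0.09 + 0.16) / v2)
    assert est.total_shares["E"][1] == pytest.approx((0.04 + 0.25) / v2)
    d = est.to_dict()
    assert d["shares"]["A"][0][0] == pytest.approx(0.36 / v1)


def test_shares_sum_to_one(small_univariate_groups):
    groups, _ = small_univariate_groups
    res = fit(build_univariate("ACE", data=groups), groups, n_starts=2,
              standard_errors=False)
    est = standardize(res)
    total = sum(est.total_shares[c][0] for c in est.components)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_univariate_recovery_with_ses(small_univariate_groups):
    """AE fit on AE-truth data: the A share lands near 0.39 and its
    delta-method CI covers the truth."""
    groups, truth = small_univariate_groups
    res = fit(build_univariate("AE", data=groups), groups, n_starts=2)
    a2 = truth.shares["A"][0]
    summ = res.summaries["A_total_w1"]
    assert summ["estimate"] == pytest.approx(a2, abs=0.06)
    assert summ["ci_lower"] <= summ["estimate"] <= summ["ci_upper"]
    assert res.se is not None and np.all(np.isfinite(res.se))


def test_standardize_requires_metadata():
    res = fit(build_univariate("AE"), [
        np.random.default_rng(0).standard_normal((50, 2)),
        np.random.default_rng(1).standard_normal((50, 2)),
    ], n_starts=1, standard_errors=False)
    res.meta = {}
    with pytest.raises(ValueError, match="no biometric structure"):
        standardize(res)


# -- property tests ----------------------------------------------------------


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(-1.0, 1.0), min_size=6, max_size=6),
       st.floats(0.01, 1.0), st.floats(0.01, 1.0))
def test_cholesky_builder_always_pd(vals, d1, d2):
    """Anywhere inside its bounds (E diagonal floored) the Cholesky builder
    produces symmetric positive-definite covariances for both groups."""
    spec = build_cholesky(2)
    theta = np.array([vals[0], vals[1], vals[2], d1, vals[3], d2,
                      vals[4], vals[5]])
    for mu, sigma in spec.builder(theta):
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
        assert np.linalg.eigvalsh(sigma).min() > 0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.05, 0.95))
def test_expected_cov_mz_cross_at_least_dz(a2, c_frac, h):
    """For any admissible ACE share split the MZ cross-twin covariance is at
    least the DZ one (A is double-weighted, C equal, E absent)."""
    c2 = (1.0 - a2) * c_frac * h
    e2 = max(1.0 - a2 - c2, 1e-6)
    s_mz, s_dz, _ = univariate_expected_cov("ACE", a2=a2, c2=c2, e2=e2)
    assert s_mz[0, 1] >= s_dz[0, 1] - 1e-12


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10**6))
def test_builder_likelihood_consistency(seed):
    """ModelSpec.builder output plugged straight into the likelihood equals
    fitting machinery's objective at the same theta (no hidden state)."""
    rng = np.random.default_rng(seed)
    groups = [rng.standard_normal((30, 2)) for _ in range(2)]
    spec = build_univariate("AE", data=groups)
    stats = [PatternStats.from_data(g) for g in groups]
    total = sum(
        neg2_loglik(mu, sig, st_)
        for (mu, sig), st_ in zip(spec.builder(spec.start), stats)
    )
    assert np.isfinite(total)
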