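"""EFA (minres, parallel analysis, quartimin) and FIML CFA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinstab.data import select_one_twin
from twinstab.factors import (
    ASSIGN_THRESHOLD,
    assign_items,
    cfa,
    cfa_spec,
    efa,
    minres,
    pairwise_corr,
    parallel_analysis,
    split_sample,
)
from twinstab.recovery import item_truth
from twinstab.simulate import simulate_items


def _true_pattern():
    lam = np.zeros((10, 2))
    lam[:6, 0] = 0.7
    lam[6:9, 1] = 0.7
    lam[9] = (0.2, 0.2)
    return lam


def _implied_corr(lam, phi):
    full = lam @ phi @ lam.T
    np.fill_diagonal(full, 1.0)
    return full


def _one_twin_items(cfg, seed=0):
    data, _ = simulate_items(cfg)
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=data.n_pairs)
    return np.where(
        (pick == 1)[:, None],
        data.df[data.item_columns(1, 1)].to_numpy(float),
        data.df[data.item_columns(2, 1)].to_numpy(float),
    )


# -- splitting ----------------------------------------------------------------


def test_split_sample_disjoint_exhaustive():
    df = pd.DataFrame({"id": np.arange(1000)})
    a, b = split_sample(df, 0.7, seed=4)
    assert len(a) == 700 and len(b) == 300
    assert set(a["id"]).isdisjoint(b["id"])
    assert set(a["id"]) | set(b["id"]) == set(df["id"])


def test_split_sample_deterministic_and_validated():
    df = pd.DataFrame({"id": np.arange(100)})
    a1, _ = split_sample(df, 0.7, seed=9)
    a2, _ = split_sample(df, 0.7, seed=9)
    assert a1.equals(a2)
    a3, _ = split_sample(df, 0.7, seed=10)
    assert not a1.equals(a3)
    with pytest.raises(ValueError):
        split_sample(df, 1.0)


# -- extraction ---------------------------------------------------------------


def test_minres_reproduces_noise_free_structure():
    """On the exact model-implied correlation matrix, minres recovers the
    communalities and reproduces the matrix to near machine precision."""
    lam, phi = _true_pattern(), np.array([[1.0, 0.6], [0.6, 1.0]])
    corr = _implied_corr(lam, phi)
    L, psi, obj = minres(corr, 2)
    assert obj < 1e-9
    off = ~np.eye(10, dtype=bool)
    np.testing.assert_allclose((L @ L.T)[off], corr[off], atol=1e-5)
    comm = np.einsum("if,fg,ig->i", lam, phi, lam)
    np.testing.assert_allclose((L**2).sum(axis=1), comm, atol=1e-4)


def test_parallel_analysis_baseline_near_one():
    """Eigenvalue baseline for pure-noise data straddles 1 and decreases."""
    pa = parallel_analysis(2000, 10, seed=2)
    assert np.all(np.diff(pa) < 0)
    assert pa[0] > 1.0 > pa[-1]
    assert pa[0] < 1.3


def test_assign_items_threshold_and_ties():
    loadings = np.array([
        [0.8, 0.1],    # factor 0
        [-0.5, 0.2],   # factor 0 (absolute value)
        [0.1, 0.45],   # factor 1
        [0.25, 0.25],  # below threshold -> unassigned
        [0.6, 0.6],    # exact tie -> unassigned
        [0.3, 0.1],    # at threshold (not above) -> unassigned
    ])
    np.testing.assert_array_equal(assign_items(loadings),
                                  [0, 0, 1, -1, -1, -1])
    assert ASSIGN_THRESHOLD == 0.3


def test_efa_recovers_six_three_structure():
    """EFA on simulated 0-4 item data retains two factors and reproduces
    the 6/3 assignment (weak item unassigned) in most replicates."""
    hits = 0
    for rep in range(5):
        items = _one_twin_items(item_truth(seed=100 + rep, n_mz=700,
                                           n_dz=1300), seed=rep)
        result = efa(items, seed=rep)
        if result.n_factors != 2:
            continue
        sizes = sorted(
            [(result.assignment == f).sum() for f in range(2)], reverse=True
        )
        if sizes == [6, 3] and result.assignment[9] == -1:
            hits += 1
    assert hits >= 4


def test_efa_factor_correlation_recovered():
    items = _one_twin_items(item_truth(seed=55, n_mz=1500, n_dz=2500), seed=1)
    result = efa(items, n_factors=2, seed=0)
    phi = abs(result.factor_corr[0, 1])
    # attenuated by discretisation of the 0-4 responses, but clearly oblique
    assert 0.35 <= phi <= 0.75
    assert result.rotation_converged


def test_efa_orthogonal_truth_gives_small_factor_correlation():
    cfg = item_truth(seed=8, n_mz=1500, n_dz=2500)
    cfg.params = dict(cfg.params)
    cfg.params["factor_corr"] = 0.0
    items = _one_twin_items(cfg, seed=2)
    result = efa(items, n_factors=2, seed=0)
    assert abs(result.factor_corr[0, 1]) < 0.1


def test_efa_fixed_count_and_fit_path():
    items = _one_twin_items(item_truth(seed=3, n_mz=400, n_dz=700), seed=3)
    result = efa(items, n_factors=1, seed=0)
    assert result.n_factors == 1
    assert result.loadings.shape == (10, 1)
    # more factors never fit worse in the minres objective
    assert result.fit_by_factors[1] >= result.fit_by_factors[2] >= (
        result.fit_by_factors[3] - 1e-12
    )
    d = result.to_dict()
    assert d["n_factors"] == 1


# -- CFA -----------------------------------------------------------------------


def _pattern_6_3():
    pattern = np.zeros((9, 2), dtype=bool)
    pattern[:6, 0] = True
    pattern[6:, 1] = True
    return pattern


def test_cfa_recovers_structure_with_good_fit():
    """CFA of the 6+3 pattern on confirmation data: loadings near truth
    (attenuated by discretisation), RMSEA below 0.05, CFI above 0.95."""
    items = _one_twin_items(item_truth(seed=31, n_mz=1000, n_dz=1800), seed=4)
    result = cfa(items[:, :9], _pattern_6_3(), seed=0)
    assert result.converged
    assert result.df == (9 * 12) // 2 - result.k
    assert result.rmsea < 0.05
    assert result.cfi > 0.95
    assert result.srmr < 0.06
    lam = result.loadings[result.loadings != 0]
    assert np.all(lam > 0.45) and np.all(lam < 0.85)
    assert 0.35 < result.factor_corr[0, 1] < 0.8


def test_cfa_one_factor_fits_worse():
    """Collapsing the two dimensions into one factor worsens AIC and chi2."""
    items = _one_twin_items(item_truth(seed=77, n_mz=1000, n_dz=1800), seed=5)
    two = cfa(items[:, :9], _pattern_6_3(), seed=0)
    one = cfa(items[:, :9], np.ones((9, 1), dtype=bool), seed=0)
    assert one.chi2 > two.chi2
    assert one.meta["aic"] > two.meta["aic"]


def test_cfa_pattern_validation():
    bad = np.zeros((5, 2), dtype=bool)
    bad[:4, 0] = True
    bad[4, 1] = True  # singleton factor
    with pytest.raises(ValueError, match="at least 2 items"):
        cfa_spec(5, bad)
    cross = np.ones((4, 2), dtype=bool)
    with pytest.raises(ValueError, match="exactly one factor"):
        cfa_spec(4, cross)


def test_pairwise_corr_handles_missing(rng):
    x = rng.standard_normal((500, 3))
    x[:, 2] = 0.8 * x[:, 0] + 0.6 * rng.standard_normal(500)
    x[rng.random((500, 3)) < 0.1] = np.nan
    corr = pairwise_corr(x)
    assert np.allclose(np.diag(corr), 1.0)
    assert corr[0, 2] > 0.5


# -- property tests ------------------------------------------------------------


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10**6), st.integers(20, 200), st.floats(0.1, 0.9))
def test_split_fraction_property(seed, n, fraction):
    df = pd.DataFrame({"id": np.arange(n)})
    a, b = split_sample(df, fraction, seed=seed)
    assert len(a) == int(round(n * fraction))
    assert len(a) + len(b) == n
    assert set(a["id"]).isdisjoint(b["id"])


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 10**6))
def test_assignment_is_permutation_equivariant(seed):
    """Swapping the factor columns swaps the assignment labels."""
    rng = np.random.default_rng(seed)
    loadings = rng.uniform(-1, 1, size=(8, 2))
    a = assign_items(loadings)
    b = assign_items(loadings[:, ::-1])
    swapped = np.where(a == -1, -1, 1 - a)
    np.testing.assert_array_equal(b, swapped)
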