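"""Dataset container, I/O, transforms, correlations and reliability."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinstab.data import (
    TwinDataset,
    cronbach_alpha,
    crosstwin_correlations,
    descriptives,
    load_csv,
    longitudinal_correlations,
    pearson_with_ci,
    select_one_twin,
    sqrt_transform,
)
from twinstab.recovery import stability_truth, univariate_truth
from twinstab.simulate import simulate


def _csv(text):
    return io.StringIO(text.strip() + "\n")


# -- I/O ---------------------------------------------------------------------


def test_load_csv_roundtrip(tmp_path, small_cpm_dataset):
    data, _ = small_cpm_dataset
    path = tmp_path / "cohort.csv"
    data.write_csv(path)
    back = load_csv(path)
    assert back.n_waves == data.n_waves
    assert back.n_vars == data.n_vars
    assert back.n_pairs == data.n_pairs
    a = data.df[data.phenotype_columns(1)].to_numpy(float)
    b = back.df[back.phenotype_columns(1)].to_numpy(float)
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_load_csv_duplicate_pair_id_rejected():
    with pytest.raises(ValueError, match="duplicated pair_id"):
        load_csv(_csv("""
pair_id,zygosity,score_w1_t1,score_w1_t2
1,MZ,1.0,2.0
1,DZ,3.0,4.0
"""))


def test_load_csv_bad_zygosity_rejected():
    with pytest.raises(ValueError, match="OS"):
        load_csv(_csv("""
pair_id,zygosity,score_w1_t1,score_w1_t2
1,MZ,1.0,2.0
2,OS,3.0,4.0
"""))


def test_load_csv_drops_all_missing_pairs(caplog):
    with caplog.at_level("WARNING"):
        data = load_csv(_csv("""
pair_id,zygosity,score_w1_t1,score_w1_t2
1,MZ,1.0,2.0
2,DZ,,
3,DZ,0.5,
"""))
    assert data.n_pairs == 2
    assert data.df["pair_id"].tolist() == [1, 3]
    assert "dropping 1 pair" in caplog.text


def test_load_csv_infers_multivariate_and_items():
    data = load_csv(_csv("""
pair_id,zygosity,score_v1_w1_t1,score_v1_w1_t2,score_v2_w1_t1,score_v2_w1_t2,item_w1_i1_t1,item_w1_i1_t2,item_w1_i2_t1,item_w1_i2_t2
1,MZ,1,2,3,4,0,1,2,3
"""))
    assert (data.n_waves, data.n_vars, data.n_items) == (1, 2, 2)


def test_load_csv_requires_data_columns():
    with pytest.raises(ValueError, match="no score or item columns"):
        load_csv(_csv("pair_id,zygosity\n1,MZ"))


# -- transforms --------------------------------------------------------------


def test_sqrt_transform_values_and_missing():
    df = pd.DataFrame({
        "pair_id": [1, 2], "zygosity": ["MZ", "DZ"],
        "score_w1_t1": [4.0, np.nan], "score_w1_t2": [9.0, 0.0],
    })
    out = sqrt_transform(TwinDataset(df=df, n_waves=1))
    assert out.df["score_w1_t1"].tolist()[:1] == [2.0]
    assert np.isnan(out.df["score_w1_t1"].iloc[1])
    assert out.df["score_w1_t2"].tolist() == [3.0, 0.0]


def test_sqrt_transform_rejects_negative():
    df = pd.DataFrame({
        "pair_id": [1], "zygosity": ["MZ"],
        "score_w1_t1": [-1.0], "score_w1_t2": [1.0],
    })
    with pytest.raises(ValueError, match="negative"):
        sqrt_transform(TwinDataset(df=df, n_waves=1))


def test_sqrt_transform_reduces_skew():
    """The generator's right-skewed raw scores come back near-normal."""
    data, _ = simulate(univariate_truth(seed=9, n_mz=4000, n_dz=4000))
    raw_skew = descriptives(data)["skewness"].iloc[0]
    tr_skew = descriptives(sqrt_transform(data))["skewness"].iloc[0]
    assert raw_skew > 0.5
    assert abs(tr_skew) < 0.1


# -- correlations ------------------------------------------------------------


def test_pearson_with_ci_against_brute_force(rng):
    x = rng.standard_normal(400)
    y = 0.6 * x + 0.8 * rng.standard_normal(400)
    x[rng.choice(400, 30, replace=False)] = np.nan
    r, lo, hi, n = pearson_with_ci(x, y)
    ok = ~np.isnan(x)
    assert n == int(ok.sum())
    expected = np.corrcoef(x[ok], y[ok])[0, 1]
    assert r == pytest.approx(expected, abs=1e-12)
    assert lo < r < hi


def test_pearson_with_ci_degenerate():
    r, lo, hi, n = pearson_with_ci(np.array([1.0, np.nan]), np.array([1.0, 2.0]))
    assert n == 1 and np.isnan(r) and np.isnan(lo) and np.isnan(hi)


def test_fisher_ci_coverage():
    """95% Fisher-z interval covers the true correlation at roughly the
    nominal rate (200 replicates, n=500, rho=0.5)."""
    rng = np.random.default_rng(123)
    rho, cover, reps = 0.5, 0, 200
    for _ in range(reps):
        x = rng.standard_normal(500)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(500)
        _, lo, hi, _ = pearson_with_ci(x, y)
        cover += lo <= rho <= hi
    assert 0.905 <= cover / reps <= 0.985


def test_stability_correlation_recovers_truth():
    """One-twin-per-pair wave-1/wave-2 correlation recovers the generating
    phenotypic stability of 0.76 after the square-root transform."""
    data, _ = simulate(stability_truth(seed=21, n_pairs=20000))
    table = longitudinal_correlations(sqrt_transform(data), one_per_pair=True)
    assert table["r"].iloc[0] == pytest.approx(0.76, abs=0.02)


def test_longitudinal_correlations_shape_and_guards(small_cpm_dataset):
    data, _ = small_cpm_dataset
    table = longitudinal_correlations(data, one_per_pair=True, seed=1)
    assert len(table) == 15  # 6 choose 2
    assert table["defined"].all()
    uni, _ = simulate(univariate_truth(seed=0, n_mz=10, n_dz=10))
    with pytest.raises(ValueError, match="at least 2 waves"):
        longitudinal_correlations(uni)


def test_select_one_twin_mixes_both_twins(small_cpm_dataset):
    data, _ = small_cpm_dataset
    frame = select_one_twin(data, seed=3)
    assert len(frame) == data.n_pairs
    t1 = data.df[data.score_column(1, 1)].to_numpy(float)
    t2 = data.df[data.score_column(1, 2)].to_numpy(float)
    got = frame[data.score_column(1, 1)].to_numpy(float)
    from1 = np.isclose(got, t1) | (np.isnan(got) & np.isnan(t1))
    from2 = np.isclose(got, t2) | (np.isnan(got) & np.isnan(t2))
    assert np.all(from1 | from2)
    assert 0.3 < np.mean(from1) < 0.7  # genuinely random pick


def test_crosstwin_double_entry_invariance(small_cpm_dataset):
    """Swapping twin labels leaves the double-entry correlation unchanged."""
    data, _ = small_cpm_dataset
    swapped = data.copy()
    c1, c2 = data.phenotype_columns(1), data.phenotype_columns(2)
    swapped.df[c1 + c2] = data.df[c2 + c1].to_numpy()
    a = crosstwin_correlations(data)
    b = crosstwin_correlations(swapped)
    np.testing.assert_allclose(a["r"], b["r"], atol=1e-12)


def test_crosstwin_correlations_match_ae_closed_form():
    """Under an additive-genetic truth with a2=0.39 the cross-twin
    correlations are 0.39 (MZ) and 0.195 (DZ)."""
    cfg = univariate_truth(seed=17, n_mz=50000, n_dz=50000)
    cfg.skew = False
    cfg.missing_rate = 0.0
    data, _ = simulate(cfg)
    ct = crosstwin_correlations(data).set_index("zygosity")["r"]
    assert ct["MZ"] == pytest.approx(0.39, abs=0.01)
    assert ct["DZ"] == pytest.approx(0.195, abs=0.01)


# -- reliability -------------------------------------------------------------


def test_cronbach_alpha_parallel_items_oracle():
    """k parallel items with loading 0.709 have inter-item correlation
    0.709**2 and Spearman-Brown alpha = k*r / (1 + (k-1)*r) ~= 0.91."""
    lam, k, n = 0.709, 10, 40000
    rng = np.random.default_rng(77)
    f = rng.standard_normal((n, 1))
    items = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal((n, k))
    rbar = lam**2
    expected = k * rbar / (1 + (k - 1) * rbar)
    assert expected == pytest.approx(0.91, abs=0.005)
    assert cronbach_alpha(items) == pytest.approx(expected, abs=0.01)


def test_cronbach_alpha_guards():
    with pytest.raises(ValueError, match="2 items"):
        cronbach_alpha(np.zeros((10, 1)))
    with pytest.raises(ValueError, match="3 complete"):
        cronbach_alpha(np.full((5, 3), np.nan))


def test_descriptives_counts(small_cpm_dataset):
    data, _ = small_cpm_dataset
    table = descriptives(data)
    assert len(table) == 6
    row = table.iloc[0]
    assert row["n_mz"] + row["n_dz"] == row["n_pairs_complete"]
    assert row["n_pairs_complete"] <= data.n_pairs


# -- property tests ----------------------------------------------------------


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12))
def test_sqrt_transform_roundtrip_property(scores):
    """sqrt then square restores any nonnegative score matrix exactly
    (within float tolerance)."""
    vals = np.array(scores)
    df = pd.DataFrame({
        "pair_id": np.arange(len(vals)),
        "zygosity": ["MZ"] * len(vals),
        "score_w1_t1": vals,
        "score_w1_t2": vals[::-1],
    })
    out = sqrt_transform(TwinDataset(df=df, n_waves=1))
    np.testing.assert_allclose(out.df["score_w1_t1"] ** 2, vals,
                               rtol=1e-12, atol=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(10, 60))
def test_pearson_ci_ordering_property(seed, n):
    """For any sample, r lies inside its own confidence interval and the
    interval lies inside [-1, 1]."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    r, lo, hi, m = pearson_with_ci(x, y)
    assert m == n
    assert -1.0 <= lo <= r <= hi <= 1.0
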