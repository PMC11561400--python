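import numpy as np
import pytest

from chronotyper.core_data import align_to_grid
from chronotyper.seasonality import (classify_collection, fisher_g_pvalue,
                                     fisher_g_test, harmonic_regression,
                                     periodogram, quartile_fractions,
                                     time_decay)


# ---------------------------------------------------------------------------
# periodogram
# ---------------------------------------------------------------------------

def test_periodogram_concentrates_on_fourier_basis_frequency():
    t = np.arange(32)
    I = periodogram(np.cos(2 * np.pi * 4 * t / 32))
    assert np.argmax(I) == 3          # k = 4
    assert I[3] / I.sum() > 0.999


def test_periodogram_matches_brute_force_dft(rng):
    x = rng.normal(size=32)
    I = periodogram(x)
    xc = x - x.mean()
    T = 32
    for k in range(1, 16):
        direct = abs(sum(xc[t] * np.exp(-2j * np.pi * k * t / T)
                         for t in range(T))) ** 2 / T
        assert I[k - 1] == pytest.approx(direct, rel=1e-9)


def test_periodogram_rejects_constant_series():
    with pytest.raises(ValueError, match="constant"):
        periodogram(np.full(12, 3.0))


# ---------------------------------------------------------------------------
# Fisher G-test
# ---------------------------------------------------------------------------

def test_pure_annual_harmonic_is_strongly_seasonal():
    t = np.arange(32)
    r = fisher_g_test(np.cos(2 * np.pi * 4 * t / 32))
    assert r.g_statistic > 0.999
    assert r.p_value < 1e-10
    assert r.dominant_period_months == pytest.approx(8.0)
    assert r.label == "seasonal"


def test_equal_ordinates_give_p_exactly_one():
    for m in (5, 10, 15, 20):
        assert fisher_g_pvalue(1.0 / m, m) == pytest.approx(1.0, abs=1e-9)


def test_p_value_monotone_decreasing_in_g():
    m = 15
    gs = np.linspace(1.0 / m + 1e-6, 1.0, 200)
    ps = [fisher_g_pvalue(g, m) for g in gs]
    assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))
    assert all(0.0 <= p <= 1.0 for p in ps)


def test_constant_series_labelled_non_seasonal_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        r = fisher_g_test(np.full(12, 2.0), votu_id="flat")
    assert r.label == "non-seasonal" and r.p_value == 1.0


def test_white_noise_rejection_rate_is_calibrated(rng):
    hits = sum(fisher_g_test(rng.normal(size=32)).p_value < 0.05
               for _ in range(500))
    assert 0.030 <= hits / 500 <= 0.075


# ---------------------------------------------------------------------------
# collection classification
# ---------------------------------------------------------------------------

def test_classify_separates_sinusoids_from_noise(matrix_factory, rng):
    t = np.arange(32)
    sin = [3.0 + 3.0 * np.sin(2 * np.pi * (t + p) / 12)
           + rng.normal(0, 1.0, 32) for p in rng.uniform(0, 12, 80)]
    noise = [3.0 + rng.normal(0, 1.0, 32) for _ in range(20)]
    am = matrix_factory(np.clip(np.vstack(sin + noise), 0, None))
    seasonal, non_seasonal, df = classify_collection(am)
    sin_ids = set(am.votu_ids[:80])
    assert len(sin_ids & set(seasonal)) >= 76
    assert set(seasonal) | set(non_seasonal) == set(am.votu_ids)


def test_all_constant_input_all_non_seasonal(matrix_factory):
    am = matrix_factory(np.ones((3, 12)))
    seasonal, non_seasonal, _ = classify_collection(am)
    assert seasonal == [] and len(non_seasonal) == 3


def test_single_votu_matrix_gives_singleton_partition(matrix_factory):
    am = matrix_factory(np.sin(2 * np.pi * np.arange(24) / 12)[None, :] + 2)
    seasonal, non_seasonal, _ = classify_collection(am)
    assert len(seasonal) + len(non_seasonal) == 1


# ---------------------------------------------------------------------------
# quartile fractionation
# ---------------------------------------------------------------------------

def test_quartiles_100_votus_split_25_50_25(matrix_factory, rng):
    am = matrix_factory(rng.uniform(0, 10, size=(100, 6)))
    q = quartile_fractions(am)
    assert (len(q["bottom"]), len(q["middle"]), len(q["top"])) == (25, 50, 25)


def test_quartiles_rank_cut_on_10_votus(matrix_factory):
    vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 6))
    am = matrix_factory(vals, ids=[f"m{i}" for i in range(1, 11)])
    q = quartile_fractions(am)
    assert q["bottom"] == ["m1", "m2"]
    assert q["top"] == ["m9", "m10"]
    assert q["middle"] == [f"m{i}" for i in range(3, 9)]


def test_quartile_ties_broken_deterministically_by_id(matrix_factory):
    am = matrix_factory(np.ones((8, 6)), ids=[f"v{i}" for i in range(8)])
    q1 = quartile_fractions(am)
    q2 = quartile_fractions(am)
    assert q1 == q2
    assert q1["bottom"] == ["v0", "v1"]


def test_quartiles_require_four_votus(matrix_factory):
    with pytest.raises(ValueError):
        quartile_fractions(matrix_factory(np.ones((3, 6))))


# ---------------------------------------------------------------------------
# time decay
# ---------------------------------------------------------------------------

def test_time_decay_identical_samples_give_zero(matrix_factory):
    am = matrix_factory(np.tile([[1.0], [2.0]], (1, 3)))
    curve = time_decay(am)
    assert curve.mean_dissimilarity.max() == pytest.approx(0.0)


def test_time_decay_pair_count_conservation(matrix_factory, rng):
    am = matrix_factory(rng.uniform(0.1, 5, size=(5, 9)))
    curve = time_decay(am)
    assert curve.n_pairs.sum() == 9 * 8 // 2


def test_time_decay_excludes_interpolated_months(matrix_factory, rng):
    am = align_to_grid(matrix_factory(rng.uniform(0.1, 5, size=(4, 5)),
                                      month_indices=[0, 1, 3, 4, 6]))
    curve = time_decay(am)
    assert curve.n_pairs.sum() == 5 * 4 // 2


def test_time_decay_invariant_to_votu_order(matrix_factory, rng):
    vals = rng.uniform(0.1, 5, size=(6, 8))
    c1 = time_decay(matrix_factory(vals))
    c2 = time_decay(matrix_factory(vals[::-1]))
    np.testing.assert_allclose(c1.mean_dissimilarity, c2.mean_dissimilarity)


def test_annual_community_has_decay_minima_at_12_and_24(matrix_factory, rng):
    t = np.arange(32)
    vals = np.clip(np.vstack([
        2 + 2 * np.sin(2 * np.pi * (t + p) / 12) + rng.normal(0, 0.1, 32)
        for p in rng.uniform(0, 12, 40)]), 0.01, None)
    curve = time_decay(matrix_factory(vals))
    by_lag = dict(zip(curve.lags.tolist(), curve.mean_dissimilarity))
    assert by_lag[12] < by_lag[6] and by_lag[12] < by_lag[18]
    assert by_lag[24] < by_lag[18] and by_lag[24] < by_lag[30]


# ---------------------------------------------------------------------------
# harmonic regression
# ---------------------------------------------------------------------------

def test_harmonic_regression_exact_recovery(matrix_factory):
    lags = np.arange(1, 32, dtype=float)
    y = 0.5 + 0.2 * np.sin(2 * np.pi * lags / 12)
    from chronotyper.seasonality import TimeDecayCurve
    curve = TimeDecayCurve(lags, y, np.ones_like(lags, dtype=int))
    fit = harmonic_regression(curve)
    assert fit["sin_coef"] == pytest.approx(0.2, abs=1e-10)
    assert fit["cos_coef"] == pytest.approx(0.0, abs=1e-10)
    assert fit["r_squared"] == pytest.approx(1.0)
    assert fit["p_value"] < 1e-10


def test_harmonic_regression_flat_curve_not_significant():
    from chronotyper.seasonality import TimeDecayCurve
    lags = np.arange(1, 20, dtype=float)
    rngl = np.random.default_rng(5)
    curve = TimeDecayCurve(lags, 0.5 + rngl.normal(0, 1e-3, lags.size),
                           np.ones_like(lags, dtype=int))
    fit = harmonic_regression(curve)
    assert fit["amplitude"] < 0.01
    assert fit["p_value"] > 0.05


def test_harmonic_amplitude_recovered_under_noise(rng):
    from chronotyper.seasonality import TimeDecayCurve
    lags = np.arange(1, 33, dtype=float)
    ok = 0
    for _ in range(100):
        y = 0.5 + 0.2 * np.sin(2 * np.pi * lags / 12) + rng.normal(0, 0.01, 32)
        fit = harmonic_regression(TimeDecayCurve(lags, y, np.ones(32, int)))
        ok += abs(fit["amplitude"] - 0.2) <= 0.03
    assert ok >= 95


def test_seasonal_fraction_decay_is_harmonic_but_noise_is_not(matrix_factory, rng):
    t = np.arange(32)
    seasonal = np.clip(np.vstack([
        2 + 2 * np.sin(2 * np.pi * (t + p) / 12) + rng.normal(0, 0.2, 32)
        for p in rng.uniform(0, 12, 30)]), 0.01, None)
    noise = rng.uniform(0.5, 4, size=(30, 32))
    fit_s = harmonic_regression(time_decay(matrix_factory(seasonal)))
    fit_n = harmonic_regression(time_decay(matrix_factory(noise)))
    assert fit_s["p_value"] < 0.01
    assert fit_n["p_value"] > 0.05
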