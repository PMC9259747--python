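import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegevt.evt import (
    chi2_gof,
    extreme_report,
    fit_weibull,
    local_maxima,
    normalize_min,
    tail_split,
)
from eegevt.features import FeatureSeries
from eegevt.preprocess import Segmentation


def _brute_local_maxima(x):
    """Oracle: collapse ties, then strict neighbor comparison."""
    vals, firsts = [], []
    for i, v in enumerate(x):
        if not vals or v != vals[-1]:
            vals.append(v)
            firsts.append(i)
    out = []
    for k in range(1, len(vals) - 1):
        if vals[k - 1] < vals[k] > vals[k + 1]:
            out.append(vals[k])
    return np.asarray(out, dtype=float)


def test_normalize_min_examples():
    np.testing.assert_allclose(normalize_min(np.array([3.0, 5.0, 4.0])), [0, 2, 1])
    np.testing.assert_allclose(normalize_min(np.full(5, 2.2)), np.zeros(5))
    x = np.random.default_rng(0).random(100)
    assert normalize_min(x).min() == 0.0
    with pytest.raises(ValueError):
        normalize_min(np.empty(0))


def test_local_maxima_examples():
    np.testing.assert_allclose(local_maxima(np.array([0, 1, 0, 2, 0.0])), [1, 2])
    assert local_maxima(np.arange(10.0)).size == 0
    # plateau contributes one value, at the plateau
    np.testing.assert_allclose(local_maxima(np.array([0, 2, 2, 1.0])), [2])
    np.testing.assert_allclose(local_maxima(np.array([0, 2, 2, 3, 0.0])), [3])


def test_local_maxima_of_dense_sinusoid():
    t = np.linspace(0, 10, 5000)
    peaks = local_maxima(3.0 * np.sin(2 * np.pi * t))
    assert len(peaks) == 10
    np.testing.assert_allclose(peaks, 3.0, rtol=1e-4)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=5), min_size=3, max_size=40))
def test_local_maxima_matches_brute_force(vals):
    x = np.asarray(vals, dtype=float)
    np.testing.assert_array_equal(local_maxima(x), _brute_local_maxima(x))


def test_tail_split_examples(rng):
    x = np.arange(1.0, 101.0)
    below, above, cut = tail_split(x, 95)
    assert cut == pytest.approx(95.05)
    assert np.all(above > cut) and np.all(below <= cut)
    assert len(above) + len(below) == 100

    _, above0, _ = tail_split(x, 0)
    assert len(above0) == 99  # everything strictly above the minimum

    draws = rng.exponential(size=1000)
    _, above_e, _ = tail_split(draws, 95)
    assert 40 <= len(above_e) <= 60

    with pytest.raises(ValueError):
        tail_split(np.full(50, 1.0))
    with pytest.raises(ValueError):
        tail_split(np.arange(10.0))


def test_fit_weibull_scale_equivariance(rng):
    x = rng.weibull(1.3, size=500) * 2.0
    f1 = fit_weibull(x, fix_location=True)
    f2 = fit_weibull(7.0 * x, fix_location=True)
    assert f2.c == pytest.approx(f1.c, rel=1e-4)
    assert f2.s == pytest.approx(7.0 * f1.s, rel=1e-4)
    assert f1.l == 0.0


def test_fit_weibull_recovers_generating_shape(rng):
    x = stats.weibull_min.rvs(0.7, scale=2.0, size=4000, random_state=rng)
    fit = fit_weibull(x, fix_location=True)
    assert fit.converged
    assert fit.c == pytest.approx(0.7, abs=0.05)
    assert fit.s == pytest.approx(2.0, rel=0.1)


def test_fit_weibull_input_validation():
    with pytest.raises(ValueError):
        fit_weibull(np.array([-1.0] + [1.0] * 30))
    with pytest.raises(ValueError):
        fit_weibull(np.ones(10))


def test_chi2_gof_zero_for_perfectly_binned_data():
    fit = fit_weibull(stats.weibull_min.rvs(1.0, size=100, random_state=1), fix_location=True)
    dist = stats.weibull_min(fit.c, loc=fit.l, scale=fit.s)
    # place observations exactly at equal-probability bin centers: O == E
    H = 10
    n_per = 10
    qs = np.concatenate([np.linspace(h / H, (h + 1) / H, n_per + 2)[1:-1][:n_per] for h in range(H)])
    data = dist.ppf(qs)
    res = chi2_gof(data, fit, H=H)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.H == H


def test_chi2_gof_is_calibrated_for_true_weibull():
    """p > 0.05 in at least 90% of 50 seeded fits of genuine Weibull data."""
    hits = 0
    for seed in range(50):
        x = stats.weibull_min.rvs(0.8, scale=1.5, size=5000, random_state=seed)
        fit = fit_weibull(x, fix_location=True)
        res = chi2_gof(x, fit)
        if res.p > 0.05:
            hits += 1
    assert hits >= 45


def test_chi2_gof_rejects_wrong_distribution(rng):
    x = rng.lognormal(0, 1.5, size=5000)
    fit = fit_weibull(x, fix_location=True)
    res = chi2_gof(x, fit)
    assert res.p < 0.01


def test_chi2_gof_requires_enough_observations():
    fit = fit_weibull(np.random.default_rng(0).weibull(1.0, 30), fix_location=True)
    with pytest.raises(ValueError):
        chi2_gof(np.arange(1.0, 11.0), fit)


def _feature_series_from_e(e):
    e = np.asarray(e, dtype=float)
    seg = Segmentation(M=len(e), interval_s=60.0)
    return FeatureSeries(E=np.repeat(e, 4), e=e, fs=4 / 60, segmentation=seg)


def _synthetic_dawp(rng, n=480, n_seiz=3, seiz_level=8.0):
    e = rng.lognormal(0.0, 0.25, size=n)
    idx = rng.choice(n, size=n_seiz, replace=False)
    e[idx] = seiz_level * np.exp(rng.normal(0, 0.1, n_seiz))
    return e, idx


def test_removing_seizures_lightens_the_tail():
    """Dropping the seizure intervals raises the fitted tail shape."""
    heavier = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        e, idx = _synthetic_dawp(rng)
        full = extreme_report(_feature_series_from_e(e), series="e")
        reduced = extreme_report(
            _feature_series_from_e(np.delete(e, idx)), series="e"
        )
        if reduced.fit.c > full.fit.c:
            heavier += 1
    assert heavier >= 8


def test_extreme_report_classifies_planted_tail():
    rng = np.random.default_rng(3)
    e, _ = _synthetic_dawp(rng)
    rep = extreme_report(_feature_series_from_e(e), series="e")
    assert rep.heavy_tailed and rep.fit.c < 1
    assert rep.n_tail == pytest.approx(0.05 * len(e), abs=3)

    calm = rng.lognormal(0.0, 0.25, size=480)
    rep2 = extreme_report(_feature_series_from_e(calm), series="e")
    assert rep2.fit.c > rep.fit.c


def test_extreme_report_series_validation():
    with pytest.raises(ValueError):
        extreme_report(_feature_series_from_e(np.arange(100.0) + 1), series="x")
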