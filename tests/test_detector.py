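import numpy as np
import pytest

from eegevt.detector import (
    DetectorConfig,
    Subject,
    detect,
    run_scheme,
    standardize,
    train_ocsvm,
)
from eegevt.features import FeatureSeries
from eegevt.preprocess import Segmentation
from eegevt.recording import Interval, Marking


def _subject_from_e(e, seizure_intervals=(), name="s"):
    e = np.asarray(e, dtype=float)
    seg = Segmentation(M=len(e), interval_s=60.0)
    feats = FeatureSeries(E=np.repeat(e, 2), e=e, fs=2 / 60, segmentation=seg)
    marking = Marking(tuple(Interval(m * 60.0, (m + 1) * 60.0, "seizure") for m in seizure_intervals))
    return Subject(features=feats, marking=marking, name=name)


def test_standardize_basic():
    xs, tr = standardize(np.array([1.0, 2.0, 3.0]))
    assert xs.mean() == pytest.approx(0.0, abs=1e-12)
    assert xs.std() == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        standardize(np.full(10, 3.0))


def test_standardize_transform_is_frozen_for_test_data(rng):
    train = rng.normal(5, 2, size=100)
    _, tr = standardize(train)
    test = np.array([5.0])
    out = tr.apply(test)
    assert out[0, 0] == pytest.approx((5.0 - train.mean()) / train.std(), rel=1e-12)


def test_training_fraction_calibration(rng):
    x = rng.standard_normal(1000)
    model = train_ocsvm(x, DetectorConfig(threshold=5.0))
    res = detect(model, x)
    # detector scores test==train data with the calibrated offset
    flagged = int(res.flags.sum())
    assert abs(flagged - 50) <= 1
    assert abs(model.train_flag_fraction - 0.05) <= 1 / 1000


def test_flagged_sets_nest_under_fixed_scores(rng):
    """On one fitted score function, a smaller threshold flags a subset."""
    x = rng.standard_normal(500)
    model = train_ocsvm(x, DetectorConfig(threshold=10.0))
    raw = model.svm.decision_function(model.transform.apply(x))
    off10 = np.quantile(raw, 0.10)
    off1 = np.quantile(raw, 0.01)
    set10 = set(np.flatnonzero(raw < off10))
    set1 = set(np.flatnonzero(raw < off1))
    assert set1 <= set10
    assert len(set1) < len(set10)


def test_planted_outliers_are_flagged():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(500)
        out_idx = rng.choice(500, size=10, replace=False)  # 2% huge outliers
        x[out_idx] = rng.uniform(50, 100, size=10)
        model = train_ocsvm(x, DetectorConfig(threshold=2.5))
        res = detect(model, x)
        if res.flags[out_idx].all():
            hits += 1
    assert hits == 10


def test_detect_median_inlier_and_far_outlier(rng):
    x = rng.standard_normal(400)
    model = train_ocsvm(x, DetectorConfig(threshold=10.0))
    res = detect(model, np.array([np.median(x), 100.0]))
    assert not res.flags[0]
    assert res.flags[1]
    assert np.array_equal(res.flags, res.scores < 0)


def test_detect_empty_test_set(rng):
    model = train_ocsvm(rng.standard_normal(100), DetectorConfig(threshold=5.0))
    res = detect(model, np.empty(0))
    assert res.scores.size == 0 and res.flags.size == 0


def test_train_requires_enough_intervals(rng):
    with pytest.raises(ValueError, match="50"):
        train_ocsvm(rng.standard_normal(30), DetectorConfig())


def test_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(threshold=0.0)
    with pytest.raises(ValueError):
        DetectorConfig(threshold=60.0)
    with pytest.raises(ValueError):
        DetectorConfig(k_folds=1)
    with pytest.raises(ValueError):
        DetectorConfig(kernel="linear")
    with pytest.raises(ValueError):
        DetectorConfig(scheme="bootstrap")


def test_cv_scores_every_interval_once(rng):
    subj = _subject_from_e(rng.lognormal(0, 0.3, size=600))
    cfg = DetectorConfig(threshold=5.0, scheme="cv", k_folds=10, seed=1)
    (res,) = run_scheme([subj], cfg)
    assert len(res.scores) == 600
    assert np.all(np.isfinite(res.scores))
    fold_of = res.provenance["fold_of"]
    counts = np.bincount(fold_of, minlength=10)
    assert np.all(counts == 60)  # 600 intervals, k=10: each fold tests 60


def test_cv_rejects_too_few_intervals(rng):
    subj = _subject_from_e(rng.lognormal(0, 0.3, size=5))
    with pytest.raises(ValueError, match="k_folds"):
        run_scheme([subj], DetectorConfig(scheme="cv", k_folds=10))


def test_cv_is_deterministic_under_fixed_seed(rng):
    subj = _subject_from_e(rng.lognormal(0, 0.3, size=200))
    cfg = DetectorConfig(threshold=2.5, scheme="cv", seed=42)
    (a,) = run_scheme([subj], cfg)
    (b,) = run_scheme([subj], cfg)
    np.testing.assert_array_equal(a.scores, b.scores)


def test_loo_excludes_held_out_subject(rng):
    """A subject whose whole scale is shifted far above the others gets all
    intervals flagged under LOO (its own extremes never enter training)."""
    normal = [_subject_from_e(rng.lognormal(0, 0.2, size=100), name=f"n{i}") for i in range(3)]
    shifted = _subject_from_e(50 + rng.lognormal(0, 0.2, size=100), name="shifted")
    cfg = DetectorConfig(threshold=5.0, scheme="loo", seed=0)
    results = run_scheme(normal + [shifted], cfg)
    assert results[-1].provenance["held_out"] == "shifted"
    assert results[-1].flags.mean() > 0.95
    # unshifted subjects are mostly inliers against the pooled model
    assert np.mean([r.flags.mean() for r in results[:-1]]) < 0.2


def test_loo_needs_two_subjects(rng):
    with pytest.raises(ValueError):
        run_scheme([_subject_from_e(rng.random(100))], DetectorConfig(scheme="loo"))
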