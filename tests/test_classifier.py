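"""Forest training, vote fractions, APT calibration, evaluation, importances."""

import numpy as np
import pandas as pd
import pytest

import aptcite as ac
from aptcite.classifier import (
    AptBin,
    BIN_TARGETS,
    assign_bins,
    binned_predicted_vs_actual,
    downsample_majority,
)
from aptcite.profiles import FEATURE_NAMES


def _planted_profiles(n, seed, noise=0.0):
    """Profiles whose label is [meanH > 0.5]; optionally noisy."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.random((n, 22)), columns=list(FEATURE_NAMES))
    y = (X["meanH"] > 0.5).astype(int).to_numpy()
    if noise:
        flip = rng.random(n) < noise
        y = np.where(flip, 1 - y, y)
    return X, y


# ---- downsampling ----------------------------------------------------------

def test_downsampling_keeps_minority_and_hits_ratio():
    rng = np.random.default_rng(0)
    y = np.array([1] * 100 + [0] * 1000)
    idx = downsample_majority(y, 2.0, rng)
    kept = y[idx]
    assert (kept == 1).sum() == 100          # every minority row survives
    assert (kept == 0).sum() == 200          # 2x the minority count
    assert len(np.unique(idx)) == len(idx)   # without replacement


def test_downsampling_single_class_is_error():
    with pytest.raises(ValueError):
        downsample_majority(np.ones(10), 2.0, np.random.default_rng(0))


# ---- training & prediction -------------------------------------------------

def test_training_learns_separable_rule():
    X, y = _planted_profiles(4000, seed=1)
    clf = ac.train(X, y, seed=2)
    raw = ac.predict_raw(clf, X)
    acc = ((raw >= 0.5).astype(int) == y).mean()
    assert acc >= 0.99


def test_training_is_deterministic():
    X, y = _planted_profiles(1500, seed=3, noise=0.1)
    Xtest, _ = _planted_profiles(300, seed=4)
    r1 = ac.predict_raw(ac.train(X, y, seed=11), Xtest)
    r2 = ac.predict_raw(ac.train(X, y, seed=11), Xtest)
    np.testing.assert_array_equal(r1, r2)


def test_training_single_class_is_error():
    X, _ = _planted_profiles(50, seed=5)
    with pytest.raises(ValueError):
        ac.train(X, np.ones(50), seed=0)


def test_raw_predictions_are_vote_fractions():
    X, y = _planted_profiles(2000, seed=6, noise=0.2)
    clf = ac.train(X, y, seed=7, n_trees=40)
    raw = ac.predict_raw(clf, X.head(200))
    assert ((raw >= 0) & (raw <= 1)).all()
    # vote fractions are multiples of 1/n_trees
    np.testing.assert_allclose(raw * 40, np.round(raw * 40), atol=1e-9)


def test_prediction_aligns_features_by_name():
    X, y = _planted_profiles(1500, seed=8)
    clf = ac.train(X, y, seed=9)
    permuted = X.head(100)[list(reversed(FEATURE_NAMES))]
    np.testing.assert_array_equal(
        ac.predict_raw(clf, X.head(100)), ac.predict_raw(clf, permuted)
    )


def test_prediction_rejects_missing_features():
    X, y = _planted_profiles(600, seed=10)
    clf = ac.train(X, y, seed=0)
    with pytest.raises(ValueError):
        ac.predict_raw(clf, X.head(5).drop(columns=["meanH"]))


# ---- APT bin calibration ---------------------------------------------------

def test_calibration_recovers_uniform_probability_bins():
    rng = np.random.default_rng(21)
    raw = rng.random(40_000)
    labels = (rng.random(40_000) < raw).astype(int)
    calib = ac.calibrate_bins(raw, labels)
    assert len(calib.bin_rates) == 5
    for rate, target in zip(calib.bin_rates, BIN_TARGETS):
        assert abs(rate - target) < 0.05
    t = calib.thresholds
    assert t[0] < t[1] < t[2] < t[3]


def test_calibration_is_rank_invariant():
    rng = np.random.default_rng(22)
    raw = rng.random(5000)
    labels = (rng.random(5000) < raw).astype(int)
    c1 = ac.calibrate_bins(raw, labels)
    c2 = ac.calibrate_bins(raw ** 3, labels)    # monotone transform
    np.testing.assert_array_equal(
        assign_bins(c1, raw), assign_bins(c2, raw ** 3)
    )


def test_calibration_degenerate_raw_is_error():
    with pytest.raises(ValueError):
        ac.calibrate_bins(np.full(100, 0.5), np.zeros(100))


def test_bins_are_monotone_in_raw_score(trained_small, small_profiles,
                                        small_corpus):
    clf, calib = trained_small
    raw = ac.predict_raw(clf, small_profiles)
    ranks = assign_bins(calib, raw)
    order = np.argsort(raw)
    assert (np.diff(ranks[order]) >= 0).all()


def test_apt_score_endpoints(trained_small):
    _, calib = trained_small
    assert assign_bins(calib, np.array([0.0]))[0] == 0     # LT5
    assert assign_bins(calib, np.array([1.0]))[0] == 4     # GT95


def test_empirical_bin_rates_monotone(trained_small, small_profiles,
                                      small_corpus):
    clf, calib = trained_small
    raw = ac.predict_raw(clf, small_profiles)
    ranks = assign_bins(calib, raw)
    y = small_corpus.labels.to_numpy()
    rates = [y[ranks == k].mean() for k in range(5) if (ranks == k).any()]
    assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))


# ---- evaluation ------------------------------------------------------------

def test_evaluate_perfect_and_flipped_predictions():
    X, y = _planted_profiles(3000, seed=30)
    clf = ac.train(X, y, seed=31)
    res = ac.evaluate(clf, X, y)
    assert res["accuracy"] >= 0.99 and res["f1"] >= 0.99
    flipped = ac.evaluate(clf, X, 1 - y)
    assert flipped["accuracy"] <= 0.01 and flipped["f1"] <= 0.01
    assert res["chance_rate"] == pytest.approx(y.mean())


def test_f1_closed_form_confusion():
    """TP=3, FP=1, FN=1, TN=5 gives F1 = 0.75 by the harmonic-mean formula."""
    from sklearn.metrics import f1_score

    y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
    assert f1_score(y_true, y_pred) == pytest.approx(0.75)


# ---- feature importance ----------------------------------------------------

def test_importance_recovers_planted_signal():
    X, y = _planted_profiles(6000, seed=40, noise=0.05)
    clf = ac.train(X, y, seed=41)
    ranked = ac.feature_importance(clf)
    assert ranked[0][0] == "meanH"
    assert sum(v for _, v in ranked) == pytest.approx(1.0)
    assert all(v >= 0 for _, v in ranked)


def test_importance_flat_under_pure_noise():
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.random((10_000, 22)), columns=list(FEATURE_NAMES))
    y = rng.integers(0, 2, size=10_000)
    clf = ac.train(X, y, seed=43)
    imp = np.array([v for _, v in ac.feature_importance(clf)])
    assert imp.max() < 3 * imp.mean()


def test_subgroup_importance_uses_subgroup_only(small_corpus, small_profiles):
    y = small_corpus.labels.to_numpy()
    fundamental = (small_profiles["H"] == 0).to_numpy() & \
                  ((small_profiles["A"] > 0) | (small_profiles["MC"] > 0)).to_numpy()
    ranked = ac.subgroup_importance(small_profiles, y, fundamental, seed=3)
    assert len(ranked) == 22


# ---- trajectories & predicted-vs-actual ------------------------------------

def test_frozen_network_trajectory_is_constant(trained_small, small_profiles):
    clf, calib = trained_small
    prof = small_profiles.iloc[5]
    snapshots = {year: prof for year in range(2002, 2008)}
    traj = ac.apt_trajectory(snapshots, clf, calib)
    raws = {s.raw for _, s in traj}
    bins = {s.bin for _, s in traj}
    assert len(raws) == 1 and len(bins) == 1


def test_trajectory_tracks_increasingly_human_citers(trained_small):
    clf, calib = trained_small
    base = pd.Series(0.0, index=list(FEATURE_NAMES))
    base[["H", "A", "MC"]] = (0.2, 0.4, 0.4)
    snaps = {}
    for i, year in enumerate(range(2001, 2007)):
        s = base.copy()
        s["CPY"] = 0.5 + 0.3 * i
        s["meanH"] = 0.1 + 0.15 * i
        s["maxH"] = min(1.0, 0.3 + 0.15 * i)
        s["meanD"] = 0.1 + 0.1 * i
        snaps[year] = s
    traj = ac.apt_trajectory(snaps, clf, calib)
    raws = [s.raw for _, s in traj]
    assert raws[-1] > raws[0]


def test_predicted_vs_actual_identity_points():
    calib = ac.BinCalibration(
        thresholds=(0.1, 0.35, 0.6, 0.9),
        bin_rates=(0.05, 0.25, 0.5, 0.75, 0.95),
        bin_counts=(1, 1, 1, 1, 1),
    )
    rng = np.random.default_rng(50)
    raw = rng.random(30_000)
    labels = (rng.random(30_000) < raw).astype(int)
    res = binned_predicted_vs_actual(calib, raw, labels)
    assert res["slope"] == pytest.approx(1.0, abs=0.1)
    assert res["r2"] > 0.95


def test_predicted_vs_actual_constant_actuals_error():
    calib = ac.BinCalibration(
        thresholds=(0.2, 0.4, 0.6, 0.8),
        bin_rates=(0, 0, 0, 0, 0), bin_counts=(1, 1, 1, 1, 1),
    )
    raw = np.linspace(0, 1, 100)
    with pytest.raises(ValueError):
        binned_predicted_vs_actual(calib, raw, np.zeros(100, dtype=int))


# ---- repeated holdout and persistence --------------------------------------

def test_repeated_holdout_reports_per_repetition(small_corpus, small_profiles):
    res = ac.repeated_holdout(
        small_profiles, small_corpus.labels,
        n_train=500, n_test=300, n_repetitions=2, seed=1, n_trees=25,
    )
    assert list(res.columns) == ["repetition", "accuracy", "f1", "auc",
                                 "chance_rate"]
    assert len(res) == 2 and res["accuracy"].between(0, 1).all()


def test_model_round_trip_and_hash_guard(tmp_path, trained_small,
                                         small_profiles):
    clf, calib = trained_small
    path = tmp_path / "model.joblib"
    ac.save_model(clf, path, calib)
    back, back_calib = ac.load_model(path)
    np.testing.assert_array_equal(
        ac.predict_raw(back, small_profiles.head(20)),
        ac.predict_raw(clf, small_profiles.head(20)),
    )
    assert back_calib.thresholds == calib.thresholds

    sidecar = path.with_suffix(path.suffix + ".json")
    corrupted = sidecar.read_text().replace('"meanH"', '"meanX"')
    sidecar.write_text(corrupted)
    with pytest.raises(ValueError):
        ac.load_model(path)
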