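"""The APT classifier: random forest + bin calibration over data profiles.

A random-forest classifier is trained on 22-feature data profiles against a
binary outcome (did the article ever receive a clinical citation), with the
majority class downsampled to twice the minority count.  Its raw output is
the fraction of trees voting for the positive class; because vote fractions
need not be linear in the true positive rate, they are calibrated into five
contiguous bins whose empirical positive rates sit at <5%, 25%, 50%, 75%
and >95% — the APT (Approximate Potential to Translate) score.

Calibration searches for the four thresholds directly: candidate cuts are
placed between distinct raw values near evenly spaced quantiles, and a
dynamic program picks the cuts minimising the summed squared deviation of
each bin's empirical positive rate from its target.  This keeps bins
contiguous in raw score, non-empty, and centred on the actual positive-rate
distribution; any rank-preserving transform of the raw scores leaves the
bin memberships unchanged.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    f1_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .profiles import FEATURE_NAMES

__all__ = [
    "AptBin",
    "AptScore",
    "BinCalibration",
    "TrainedClassifier",
    "BIN_TARGETS",
    "train",
    "downsample_majority",
    "predict_raw",
    "calibrate_bins",
    "assign_bins",
    "apt_score",
    "evaluate",
    "feature_importance",
    "subgroup_importance",
    "apt_trajectory",
    "predicted_vs_actual",
    "binned_predicted_vs_actual",
    "repeated_holdout",
    "save_model",
    "load_model",
    "FEATURE_SUBSETS",
]


class AptBin(Enum):
    """The five APT bins; ``value`` is the nominal odds of clinical citation."""

    LT5 = 0.05
    P25 = 0.25
    P50 = 0.50
    P75 = 0.75
    GT95 = 0.95

    @property
    def rank(self) -> int:
        return list(AptBin).index(self)


#: target per-bin positive rates, LT5 → GT95
BIN_TARGETS = np.array([b.value for b in AptBin])


@dataclass(frozen=True)
class AptScore:
    raw: float          # fraction of trees voting positive, in [0, 1]
    bin: AptBin


@dataclass(frozen=True)
class BinCalibration:
    """Four strictly increasing raw-score thresholds and the rates achieved."""

    thresholds: tuple[float, float, float, float]
    bin_rates: tuple[float, float, float, float, float]
    bin_counts: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (0.0 <= t[0] < t[1] < t[2] < t[3] <= 1.0):
            raise ValueError(f"thresholds not strictly increasing: {t}")


@dataclass
class TrainedClassifier:
    """A fitted forest plus the canonical feature list and training metadata."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    seed: int
    n_train: int
    downsample_factor: float
    n_trees: int
    metadata: dict = field(default_factory=dict)


FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_NAMES,
    # article-only baselines: content alone, then content + modifier flags
    "hamc": ("H", "A", "MC"),
    "hamc+flags": ("H", "A", "MC", "D", "E", "CD"),
    "article": ("H", "A", "MC", "D", "E", "CD", "CPY"),
}


def _as_matrix(
    profiles: pd.DataFrame | np.ndarray, feature_names: Sequence[str]
) -> np.ndarray:
    """Align a profile table to a feature list by name; order-insensitive."""
    if isinstance(profiles, pd.DataFrame):
        missing = set(feature_names) - set(profiles.columns)
        if missing:
            raise ValueError(f"profiles missing features: {sorted(missing)}")
        return profiles[list(feature_names)].to_numpy(dtype=float)
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} features, got {arr.shape[1]}"
        )
    return arr


def downsample_majority(
    labels: np.ndarray, factor: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices keeping all minority rows and ``factor ×`` minority majority rows.

    Sampling is uniform without replacement; if the majority class is
    already within the factor, everything is kept.
    """
    labels = np.asarray(labels).astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for training")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    keep_n = min(len(majority), int(round(factor * len(minority))))
    kept_majority = rng.choice(majority, size=keep_n, replace=False)
    idx = np.concatenate([minority, kept_majority])
    idx.sort()
    return idx


def train(
    profiles: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int,
    *,
    downsample_factor: float = 2.0,
    n_trees: int = 100,
    feature_subset: Sequence[str] | str | None = None,
    n_jobs: int = 1,
) -> TrainedClassifier:
    """Fit the random forest with seeded majority-class downsampling.

    ``feature_subset`` may be a named mask from :data:`FEATURE_SUBSETS`
    or an explicit tuple of feature names; default is all 22 features.
    Deterministic given ``seed``.
    """
    if isinstance(feature_subset, str):
        feature_subset = FEATURE_SUBSETS[feature_subset]
    names = tuple(feature_subset) if feature_subset else (
        tuple(profiles.columns) if isinstance(profiles, pd.DataFrame)
        else FEATURE_NAMES
    )
    X = _as_matrix(profiles, names)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("profiles and labels differ in length")

    rng = np.random.default_rng(seed)
    idx = downsample_majority(y, downsample_factor, rng)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=n_jobs,
    )
    model.fit(X[idx], y[idx])
    return TrainedClassifier(
        model=model,
        feature_names=names,
        seed=seed,
        n_train=len(idx),
        downsample_factor=downsample_factor,
        n_trees=n_trees,
    )


def predict_raw(
    clf: TrainedClassifier, profiles: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Fraction of trees voting positive for each profile, in [0, 1].

    Columns are aligned to the classifier's feature list by name, so a
    permuted-but-complete profile table scores identically.
    """
    X = _as_matrix(profiles, clf.feature_names)
    votes = np.zeros(X.shape[0])
    pos_col = int(np.flatnonzero(clf.model.classes_ == 1)[0])
    for tree in clf.model.estimators_:
        votes += tree.predict_proba(X)[:, pos_col] > 0.5
    return votes / len(clf.model.estimators_)


# ---- APT bin calibration ---------------------------------------------------

def calibrate_bins(
    raw: np.ndarray,
    labels: np.ndarray,
    *,
    max_candidates: int = 400,
) -> BinCalibration:
    """Fit the five-bin APT calibration on held-out (raw, label) pairs.

    Candidate thresholds are midpoints between consecutive *distinct* raw
    values, thinned to at most ``max_candidates`` near even quantiles; a
    dynamic program then selects the four cuts minimising

        Σ_bins (empirical positive rate − target)²,

    targets (0.05, 0.25, 0.50, 0.75, 0.95), all bins non-empty.
    """
    raw = np.asarray(raw, dtype=float)
    labels = np.asarray(labels).astype(int)
    if raw.shape != labels.shape:
        raise ValueError("raw and labels differ in shape")
    order = np.argsort(raw, kind="stable")
    r, y = raw[order], labels[order]
    n = len(r)
    # boundaries between distinct raw values (positions splitting the sorted
    # array); a degenerate distribution has none
    distinct = np.flatnonzero(np.diff(r) > 0) + 1
    if len(distinct) < 4:
        raise ValueError("raw scores too degenerate to form 5 bins")
    if len(distinct) > max_candidates:
        want = np.linspace(0, n, max_candidates + 1)[1:-1]
        pick = np.unique(np.searchsorted(distinct, want).clip(0, len(distinct) - 1))
        distinct = distinct[pick]
    # cut positions: 0 and n delimit the outer bins
    cuts = np.concatenate([[0], distinct, [n]])
    cum_pos = np.concatenate([[0], np.cumsum(y)])

    m = len(cuts)
    # cost[i, j]: squared deviation of bin (cuts[i], cuts[j]] from its target
    # depends on which bin slot it is, so compute rates once
    starts = cuts[:, None]
    ends = cuts[None, :]
    sizes = (ends - starts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = (cum_pos[ends] - cum_pos[starts]) / sizes

    INF = np.inf
    n_bins = len(BIN_TARGETS)
    # dp[j] after filling k bins ending at cut j
    dp = np.full(m, INF)
    back = np.full((n_bins, m), -1, dtype=int)
    for k in range(n_bins):
        cost_k = np.where(sizes > 0, (rates - BIN_TARGETS[k]) ** 2, INF)
        if k == 0:
            new = cost_k[0, :].copy()
            new[0] = INF  # first bin cannot be empty
        else:
            # new[j] = min_i dp[i] + cost_k[i, j] over i < j
            total = dp[:, None] + cost_k
            total[~np.tril(np.ones((m, m), dtype=bool), -1).T] = INF
            back[k] = np.argmin(total, axis=0)
            new = total[back[k], np.arange(m)]
        dp = new
    if not np.isfinite(dp[m - 1]):
        raise ValueError("could not form 5 non-empty bins")

    # backtrack the cut positions
    cut_idx = [m - 1]
    j = m - 1
    for k in range(n_bins - 1, 0, -1):
        j = int(back[k][j])
        cut_idx.append(j)
    cut_idx = cut_idx[::-1][:-1]  # the 4 interior cuts
    positions = [int(cuts[j]) for j in cut_idx]
    thresholds = tuple(
        float((r[p - 1] + r[p]) / 2.0) for p in positions
    )
    bounds = [0, *positions, n]
    bin_counts = tuple(int(bounds[i + 1] - bounds[i]) for i in range(n_bins))
    bin_rates = tuple(
        float((cum_pos[bounds[i + 1]] - cum_pos[bounds[i]]) / bin_counts[i])
        for i in range(n_bins)
    )
    return BinCalibration(thresholds=thresholds, bin_rates=bin_rates,
                          bin_counts=bin_counts)


def assign_bins(calib: BinCalibration, raw: np.ndarray) -> np.ndarray:
    """Vector of bin ranks (0 = LT5 … 4 = GT95) for raw scores."""
    return np.searchsorted(np.asarray(calib.thresholds), np.asarray(raw),
                           side="right")


def apt_score(
    clf: TrainedClassifier,
    calib: BinCalibration,
    profile: pd.DataFrame | pd.Series | np.ndarray,
) -> AptScore | list[AptScore]:
    """Raw vote fraction + calibrated bin; list for multi-row input."""
    if isinstance(profile, pd.Series):
        profile = profile.to_frame().T
    raw = predict_raw(clf, profile)
    ranks = assign_bins(calib, raw)
    bins = list(AptBin)
    scores = [AptScore(float(r), bins[k]) for r, k in zip(raw, ranks)]
    return scores[0] if len(scores) == 1 else scores


# ---- evaluation ------------------------------------------------------------

def evaluate(
    clf: TrainedClassifier,
    profiles: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
    *,
    threshold: float = 0.5,
) -> dict:
    """Held-out metrics: accuracy, F1, ROC/PR curves, AUC, chance rate.

    The caller is responsible for keeping the test set disjoint from
    training; positive class = clinically cited.
    """
    y = np.asarray(labels).astype(int)
    raw = predict_raw(clf, profiles)
    pred = (raw >= threshold).astype(int)
    fpr, tpr, roc_thr = roc_curve(y, raw)
    prec, rec, pr_thr = precision_recall_curve(y, raw)
    return {
        "accuracy": float(accuracy_score(y, pred)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "auc": float(roc_auc_score(y, raw)) if len(np.unique(y)) > 1 else float("nan"),
        "roc_curve": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr},
        "pr_curve": {"precision": prec, "recall": rec, "thresholds": pr_thr},
        "pr_auc": float(auc(rec, prec)),
        "chance_rate": float(y.mean()),
        "n": int(len(y)),
    }


def feature_importance(clf: TrainedClassifier) -> list[tuple[str, float]]:
    """Features ranked by mean decrease in Gini impurity, normalised to 1."""
    imp = np.asarray(clf.model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    ranked = sorted(zip(clf.feature_names, imp), key=lambda t: -t[1])
    return [(name, float(v)) for name, v in ranked]


def subgroup_importance(
    profiles: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    subgroup_mask: np.ndarray,
    seed: int,
    **train_kwargs,
) -> list[tuple[str, float]]:
    """Importances from a forest retrained on one article subgroup only
    (e.g. fundamental or human-focused articles)."""
    mask = np.asarray(subgroup_mask, dtype=bool)
    sub = train(profiles.loc[mask], np.asarray(labels)[mask], seed,
                **train_kwargs)
    return feature_importance(sub)


def apt_trajectory(
    snapshots: Mapping[int, pd.Series | np.ndarray],
    clf: TrainedClassifier,
    calib: BinCalibration,
) -> list[tuple[int, AptScore]]:
    """APT score of one article under a fixed classifier, year by year.

    ``snapshots`` maps year → the article's profile built from the citing
    network as of that year (cumulative).  A frozen network therefore
    yields a constant series.
    """
    out: list[tuple[int, AptScore]] = []
    for year in sorted(snapshots):
        prof = snapshots[year]
        if isinstance(prof, pd.Series):
            prof = prof.to_frame().T
        raw = float(predict_raw(clf, prof)[0])
        k = int(assign_bins(calib, np.array([raw]))[0])
        out.append((year, AptScore(raw, list(AptBin)[k])))
    return out


def predicted_vs_actual(
    clf: TrainedClassifier,
    calib: BinCalibration,
    profiles: pd.DataFrame | np.ndarray,
    labels: pd.Series | np.ndarray,
) -> dict:
    """Per-bin predicted vs actual positive rates, with slope and r².

    Predicted rate per bin is the mean raw vote fraction of its members;
    actual rate is the mean label.  Least squares of actual on predicted
    across the non-empty bins gives slope and r²; r² is undefined (error)
    when the actual rates are constant.
    """
    return binned_predicted_vs_actual(calib, predict_raw(clf, profiles), labels)


def binned_predicted_vs_actual(
    calib: BinCalibration,
    raw: np.ndarray,
    labels: pd.Series | np.ndarray,
) -> dict:
    """:func:`predicted_vs_actual` on precomputed raw scores."""
    y = np.asarray(labels).astype(int)
    raw = np.asarray(raw, dtype=float)
    ranks = assign_bins(calib, raw)
    pts = []
    for k, b in enumerate(AptBin):
        in_bin = ranks == k
        if in_bin.any():
            pts.append((b, float(raw[in_bin].mean()), float(y[in_bin].mean()),
                        int(in_bin.sum())))
    if len(pts) < 2:
        raise ValueError("need ≥2 non-empty bins for a regression")
    pred = np.array([p[1] for p in pts])
    act = np.array([p[2] for p in pts])
    if np.allclose(act, act[0]):
        raise ValueError("actual rates constant; r² undefined")
    slope, intercept = np.polyfit(pred, act, 1)
    resid = act - (slope * pred + intercept)
    r2 = 1.0 - resid.var() / act.var()
    return {
        "bins": [{"bin": b.name, "predicted": p, "actual": a, "n": n}
                 for b, p, a, n in pts],
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(r2),
    }


def repeated_holdout(
    profiles: pd.DataFrame,
    labels: pd.Series,
    *,
    n_train: int,
    n_test: int,
    n_repetitions: int = 10,
    seed: int = 0,
    **train_kwargs,
) -> pd.DataFrame:
    """Repeated independent train/test draws; one metrics row per repetition.

    Each repetition draws a fresh disjoint train/test split (without
    replacement within a repetition) from the corpus, mirroring the
    repeated-holdout validation protocol; sizes are configurable down to
    desk scale.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n_train + n_test > n:
        raise ValueError("n_train + n_test exceeds corpus size")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repetitions):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:n_train + n_test]
        clf = train(profiles.iloc[tr], y[tr],
                    seed=int(rng.integers(2**31 - 1)), **train_kwargs)
        res = evaluate(clf, profiles.iloc[te], y[te])
        rows.append({"repetition": rep, "accuracy": res["accuracy"],
                     "f1": res["f1"], "auc": res["auc"],
                     "chance_rate": res["chance_rate"]})
    return pd.DataFrame(rows)


# ---- persistence -----------------------------------------------------------

def _feature_hash(names: Iterable[str]) -> str:
    return hashlib.sha256("\x1f".join(names).encode()).hexdigest()


def save_model(
    clf: TrainedClassifier,
    path: str | Path,
    calib: BinCalibration | None = None,
) -> None:
    """Persist the forest (joblib blob) + a JSON sidecar of metadata.

    The sidecar carries the feature names, seed and calibration thresholds
    plus a hash of the feature list; loading verifies the hash.
    """
    path = Path(path)
    joblib.dump(clf.model, path)
    sidecar = {
        "format_version": 1,
        "feature_names": list(clf.feature_names),
        "feature_hash": _feature_hash(clf.feature_names),
        "seed": clf.seed,
        "n_train": clf.n_train,
        "downsample_factor": clf.downsample_factor,
        "n_trees": clf.n_trees,
        "calibration": None if calib is None else {
            "thresholds": list(calib.thresholds),
            "bin_rates": list(calib.bin_rates),
            "bin_counts": list(calib.bin_counts),
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def load_model(path: str | Path) -> tuple[TrainedClassifier, BinCalibration | None]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    names = tuple(sidecar["feature_names"])
    if _feature_hash(names) != sidecar["feature_hash"]:
        raise ValueError("feature-name hash mismatch; refusing to predict")
    model = joblib.load(path)
    clf = TrainedClassifier(
        model=model,
        feature_names=names,
        seed=sidecar["seed"],
        n_train=sidecar["n_train"],
        downsample_factor=sidecar["downsample_factor"],
        n_trees=sidecar["n_trees"],
    )
    calib = None
    if sidecar.get("calibration"):
        c = sidecar["calibration"]
        calib = BinCalibration(tuple(c["thresholds"]), tuple(c["bin_rates"]),
                               tuple(c["bin_counts"]))
    return clf, calib
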