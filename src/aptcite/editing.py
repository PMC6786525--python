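"""Citation editing: gain/loss-of-function perturbation of citing networks.

To ask *what it is about a growing citing network* that moves an article's
APT score, the citations acquired between two snapshot years are deleted
and replaced by an equal number of artificial citers with controlled
content, and the article is re-scored:

* ``ORIGINALS``  — citers resampled (with replacement) from the earlier
  network: composition unchanged, only the citation rate grows;
* ``MOLCELL`` / ``ANIMAL`` / ``HUMAN`` — homogeneous citers at the named
  triangle vertex (that score 1, everything else 0);
* ``HUMAN_PLUS`` — human-vertex citers that additionally carry all three
  modifier flags (D = E = CD = 1), the strongest clinical-looking citer
  admissible.

Network size is conserved across every edit, so any APT change reflects
citer *content* (or, for ORIGINALS, rate alone).  An ``replace_all`` flag
swaps out the entire network instead of just the increment.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import (
    AptBin,
    AptScore,
    BinCalibration,
    TrainedClassifier,
    assign_bins,
    predict_raw,
)
from .profiles import FEATURE_NAMES, NETWORK_FEATURES

__all__ = [
    "EditType",
    "EditResult",
    "select_apt_up",
    "edit_network",
    "run_editing_experiment",
    "profile_from_citers",
    "vertex_stratum",
    "write_edit_results_tsv",
]

#: citer feature columns used throughout this module
CITER_COLS = ("h", "a", "mc", "d", "e", "cd")


class EditType(Enum):
    ORIGINALS = "originals"
    MOLCELL = "molcell"
    ANIMAL = "animal"
    HUMAN = "human"
    HUMAN_PLUS = "human_plus"


#: (h, a, mc, d, e, cd) of each homogeneous synthetic citer type
_SYNTHETIC_CITER = {
    EditType.MOLCELL: (0.0, 0.0, 1.0, 0, 0, 0),
    EditType.ANIMAL: (0.0, 1.0, 0.0, 0, 0, 0),
    EditType.HUMAN: (1.0, 0.0, 0.0, 0, 0, 0),
    EditType.HUMAN_PLUS: (1.0, 0.0, 0.0, 1, 1, 1),
}


@dataclass(frozen=True)
class EditResult:
    article_id: str
    edit: EditType
    apt_before: AptScore
    apt_after: AptScore

    @property
    def delta_raw(self) -> float:
        return self.apt_after.raw - self.apt_before.raw

    @property
    def delta_bin_value(self) -> float:
        return self.apt_after.bin.value - self.apt_before.bin.value


def select_apt_up(
    bins_year_a: pd.Series,
    bins_year_b: pd.Series,
    from_bin: AptBin = AptBin.P25,
) -> pd.Index:
    """Articles sitting in ``from_bin`` at year A and strictly higher at B.

    Inputs are per-article bin ranks (0–4) or :class:`AptBin` values,
    aligned by article id.
    """

    def ranks(s: pd.Series) -> pd.Series:
        return s.map(lambda b: b.rank if isinstance(b, AptBin) else int(b))

    a, b = ranks(bins_year_a), ranks(bins_year_b).reindex(bins_year_a.index)
    mask = (a == from_bin.rank) & (b > a)
    return bins_year_a.index[mask.fillna(False)]


def edit_network(
    citers_year_a: np.ndarray,
    citers_year_b: np.ndarray,
    edit: EditType,
    rng: np.random.Generator,
    *,
    replace_all: bool = False,
) -> np.ndarray:
    """Replace the year-A→B citation increment with synthetic citers.

    Inputs are (n, 6) arrays of citer features in :data:`CITER_COLS`
    order; the year-B network must contain the year-A one as its prefix
    (cumulative snapshots).  Returns the edited (n_b, 6) network: size is
    always conserved at the natural year-B size.
    """
    a = np.asarray(citers_year_a, dtype=float).reshape(-1, len(CITER_COLS))
    b = np.asarray(citers_year_b, dtype=float).reshape(-1, len(CITER_COLS))
    if len(b) < len(a):
        raise ValueError("year-B network smaller than year-A network")
    if replace_all:
        kept = np.empty((0, len(CITER_COLS)))
        k = len(b)
    else:
        kept = a
        k = len(b) - len(a)
    if edit is EditType.ORIGINALS:
        if len(a) == 0:
            raise ValueError("ORIGINALS edit needs a non-empty year-A network")
        idx = rng.integers(0, len(a), size=k)
        synthetic = a[idx]
    else:
        synthetic = np.tile(_SYNTHETIC_CITER[edit], (k, 1)).astype(float)
    return np.vstack([kept, synthetic])


def profile_from_citers(
    article_row: pd.Series,
    citers: np.ndarray,
    pub_year: int,
    as_of_year: int,
) -> pd.Series:
    """Rebuild a 22-feature profile from an explicit citer array.

    ``article_row`` supplies the seven article features (h, a, mc, d, e,
    cd); CPY and the fifteen network summaries are recomputed from
    ``citers`` with the usual conventions (population SD, elapsed-years+1
    denominator).
    """
    citers = np.asarray(citers, dtype=float).reshape(-1, len(CITER_COLS))
    n = len(citers)
    vals = dict.fromkeys(NETWORK_FEATURES, 0.0)
    if n:
        mx = citers.max(axis=0)
        mean = citers.mean(axis=0)
        sd = citers.std(axis=0)
        for i, label in enumerate(("H", "A", "MC")):
            vals[f"max{label}"] = mx[i]
            vals[f"mean{label}"] = mean[i]
            vals[f"sd{label}"] = sd[i]
        for i, label in enumerate(("D", "E", "CD"), start=3):
            vals[f"mean{label}"] = mean[i]
            vals[f"sd{label}"] = sd[i]
    cpy = n / max(1, as_of_year - pub_year + 1) if n else 0.0
    data = {
        "H": article_row["h"], "A": article_row["a"], "MC": article_row["mc"],
        "D": float(article_row["d"]), "E": float(article_row["e"]),
        "CD": float(article_row["cd"]), "CPY": cpy,
    }
    data.update(vals)
    return pd.Series(data, index=list(FEATURE_NAMES))


def vertex_stratum(article_row: pd.Series, threshold: float = 0.95) -> str:
    """Triangle-vertex stratum: ≥95% of HAMC content in a single category."""
    for name in ("h", "a", "mc"):
        if article_row[name] >= threshold:
            return name.upper()
    return "interior"


def _citer_arrays(
    scores: pd.DataFrame,
    edges: pd.DataFrame,
    article_ids: Sequence[str],
    as_of_year: int,
) -> dict[str, np.ndarray]:
    """Per-article citer feature arrays from cumulative edges ≤ as_of_year.

    Edge order is preserved, so the year-A array is a prefix of the year-B
    array for cumulative snapshots (a precondition of the editing step).
    """
    wanted = set(article_ids)
    ed = edges[(edges["year"] <= as_of_year) & edges["cited_id"].isin(wanted)]
    feats = scores.loc[ed["citing_id"], list(CITER_COLS)].to_numpy(dtype=float)
    out: dict[str, np.ndarray] = {
        aid: np.empty((0, len(CITER_COLS))) for aid in article_ids
    }
    for aid, grp_idx in ed.groupby("cited_id", sort=False).indices.items():
        out[aid] = feats[grp_idx]
    return out


def run_editing_experiment(
    scores: pd.DataFrame,
    edges: pd.DataFrame,
    article_ids: Sequence[str],
    clf: TrainedClassifier,
    calib: BinCalibration,
    *,
    year_a: int,
    year_b: int,
    edits: Iterable[EditType] = tuple(EditType),
    seed: int = 0,
    replace_all: bool = False,
    require_year_a_citations: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every article before/after each edit; return (summary, results).

    The "before" state is the natural year-B network; each edit rebuilds
    that network, re-derives the profile, and re-scores it with the fixed
    classifier and calibration.  ``results`` has one row per article×edit;
    ``summary`` aggregates mean Δraw and mean Δbin-value per edit type and
    per vertex stratum.  Articles without a year-A citing network are
    dropped by default (the ORIGINALS resampling control is undefined for
    them).
    """
    if year_b <= year_a:
        raise ValueError("year_b must follow year_a")
    article_ids = list(article_ids)
    rng = np.random.default_rng(seed)
    nets_a = _citer_arrays(scores, edges, article_ids, year_a)
    nets_b = _citer_arrays(scores, edges, article_ids, year_b)
    if require_year_a_citations:
        article_ids = [aid for aid in article_ids if len(nets_a[aid]) > 0]
        if not article_ids:
            raise ValueError("no selected article has a year-A citing network")

    edits = list(edits)
    bins = list(AptBin)
    block_rows: list[pd.Series] = []
    for aid in article_ids:
        art = scores.loc[aid]
        pub_year = int(art["pub_year"])
        block_rows.append(
            profile_from_citers(art, nets_b[aid], pub_year, year_b)
        )
        for edit in edits:
            edited = edit_network(nets_a[aid], nets_b[aid], edit, rng,
                                  replace_all=replace_all)
            block_rows.append(
                profile_from_citers(art, edited, pub_year, year_b)
            )
    block = pd.DataFrame(block_rows).reset_index(drop=True)
    raw = predict_raw(clf, block)
    rank = assign_bins(calib, raw)

    rows = []
    stride = 1 + len(edits)
    for j, aid in enumerate(article_ids):
        base = j * stride
        before = AptScore(float(raw[base]), bins[int(rank[base])])
        stratum = vertex_stratum(scores.loc[aid])
        for i, edit in enumerate(edits, start=1):
            after = AptScore(float(raw[base + i]), bins[int(rank[base + i])])
            res = EditResult(aid, edit, before, after)
            rows.append({
                "article_id": aid,
                "vertex_stratum": stratum,
                "edit": edit.value,
                "apt_before_bin": before.bin.name,
                "apt_after_bin": after.bin.name,
                "raw_before": before.raw,
                "raw_after": after.raw,
                "delta_raw": res.delta_raw,
                "delta_bin_value": res.delta_bin_value,
                "moved_up": after.bin.rank > before.bin.rank,
            })
    results = pd.DataFrame(rows)
    summary = (
        results.groupby(["edit", "vertex_stratum"])
        .agg(
            n=("article_id", "size"),
            mean_delta_raw=("delta_raw", "mean"),
            mean_delta_bin_value=("delta_bin_value", "mean"),
            frac_moved_up=("moved_up", "mean"),
        )
        .reset_index()
    )
    return summary, results


def write_edit_results_tsv(results: pd.DataFrame, path: str | Path) -> None:
    cols = ["article_id", "vertex_stratum", "edit", "apt_before_bin",
            "apt_after_bin", "delta_raw", "delta_bin_value"]
    results[cols].to_csv(path, sep="\t", index=False)
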