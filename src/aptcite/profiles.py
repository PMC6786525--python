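"""Data profiles: the 22-feature vector fed to the APT classifier.

Seven features describe the article itself — its fractional H/A/MC content,
the binary D/E/CD modifier flags, and its citation rate (CPY, cites per
year) — and fifteen summarise the *citing network*, the set of articles
citing it: max/mean/SD of the citers' H, A and MC scores and mean/SD of
their D, E and CD flags.  The citing network can be truncated to what was
known some number of years after publication, which is how early-prediction
experiments are run.

Conventions (the upstream data formats fix none of these):

* the window ``w`` keeps citations with ``citation_year − pub_year ≤ w``;
* CPY divides by elapsed calendar years + 1, floored at 1, so an article
  cited only in its publication year still has a finite rate;
* SDs are population SDs (÷ n), zero for n ≤ 1;
* citers with no HAMC terms contribute (0, 0, 0) to the HAMC summaries but
  still count toward the flag means and toward CPY, keeping n consistent
  across all fifteen network fields;
* duplicate edges are kept as distinct observations.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import ArticleRecord, MeshVocabulary
from .scoring import CategoryFlags, HamcScore, score_article

__all__ = [
    "CitationEdge",
    "NetworkSummary",
    "DataProfile",
    "FEATURE_NAMES",
    "ARTICLE_FEATURES",
    "NETWORK_FEATURES",
    "restrict_network",
    "citation_rate",
    "summarize_network",
    "build_profile",
    "build_profiles",
    "score_table",
    "read_edges_tsv",
    "write_edges_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

#: the 7 article-level features, in canonical order
ARTICLE_FEATURES = ("H", "A", "MC", "D", "E", "CD", "CPY")
#: the 15 citing-network summaries, in canonical order
NETWORK_FEATURES = (
    "maxH", "meanH", "sdH",
    "maxA", "meanA", "sdA",
    "maxMC", "meanMC", "sdMC",
    "meanD", "sdD",
    "meanE", "sdE",
    "meanCD", "sdCD",
)
#: canonical order of the full 22-feature data profile
FEATURE_NAMES = ARTICLE_FEATURES + NETWORK_FEATURES


@dataclass(frozen=True)
class CitationEdge:
    """One citation: ``citing_id`` cites ``cited_id`` in ``year``."""

    citing_id: str
    cited_id: str
    year: int


@dataclass(frozen=True)
class NetworkSummary:
    """Max/mean/SD summaries of a citing network's content scores."""

    maxH: float = 0.0
    meanH: float = 0.0
    sdH: float = 0.0
    maxA: float = 0.0
    meanA: float = 0.0
    sdA: float = 0.0
    maxMC: float = 0.0
    meanMC: float = 0.0
    sdMC: float = 0.0
    meanD: float = 0.0
    sdD: float = 0.0
    meanE: float = 0.0
    sdE: float = 0.0
    meanCD: float = 0.0
    sdCD: float = 0.0
    is_empty: bool = False

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in NETWORK_FEATURES)


@dataclass(frozen=True)
class DataProfile:
    """Article features + network summary; flattens to the canonical 22."""

    h: float
    a: float
    mc: float
    d: int
    e: int
    cd: int
    cpy: float
    network: NetworkSummary = field(default_factory=lambda: NetworkSummary(is_empty=True))

    def flatten(self) -> np.ndarray:
        vec = np.array(
            (self.h, self.a, self.mc, self.d, self.e, self.cd, self.cpy)
            + self.network.as_tuple(),
            dtype=float,
        )
        assert vec.shape == (len(FEATURE_NAMES),)
        return vec

    def as_series(self) -> pd.Series:
        return pd.Series(self.flatten(), index=list(FEATURE_NAMES))


def restrict_network(
    edges: Iterable[CitationEdge],
    cited_article: ArticleRecord,
    *,
    window_years: float | None = None,
    as_of_year: int | None = None,
    exclude_clinical: bool = False,
    clinical_ids: set[str] | None = None,
) -> list[CitationEdge]:
    """Keep the citations of one article visible within a time window.

    Exactly one of ``window_years`` (offset from publication, inclusive:
    ``citation_year − pub_year ≤ window_years``) or ``as_of_year``
    (calendar cut-off, inclusive) must be given.  ``exclude_clinical``
    drops edges whose citing article is clinical (robustness control);
    it requires ``clinical_ids``.
    """
    if (window_years is None) == (as_of_year is None):
        raise ValueError("give exactly one of window_years / as_of_year")
    if window_years is not None:
        if window_years < 0:
            raise ValueError("window_years must be ≥ 0")
        cutoff = cited_article.pub_year + window_years
    else:
        if as_of_year < cited_article.pub_year:
            raise ValueError("as_of_year precedes publication year")
        cutoff = as_of_year
    if exclude_clinical and clinical_ids is None:
        raise ValueError("exclude_clinical requires clinical_ids")

    kept = [
        e
        for e in edges
        if e.cited_id == cited_article.article_id and e.year <= cutoff
    ]
    if exclude_clinical:
        kept = [e for e in kept if e.citing_id not in clinical_ids]
    return kept


def citation_rate(n_citations: int, pub_year: int, as_of_year: int) -> float:
    """Citations per year: count over elapsed years + 1, floored at 1."""
    if as_of_year < pub_year:
        raise ValueError("as_of_year precedes publication year")
    if n_citations == 0:
        return 0.0
    return n_citations / max(1, as_of_year - pub_year + 1)


def summarize_network(
    citers: Sequence[tuple[HamcScore, CategoryFlags]]
) -> NetworkSummary:
    """Max/mean/population-SD of the citing articles' scores and flags.

    Empty input yields all-zero fields with ``is_empty`` set.  Undefined
    HAMC scores enter the H/A/MC summaries as zeros.
    """
    if not citers:
        return NetworkSummary(is_empty=True)
    cols = np.array(
        [
            (s.h, s.a, s.mc, f.d, f.e, f.cd)
            for s, f in citers
        ],
        dtype=float,
    )
    mx = cols.max(axis=0)
    mean = cols.mean(axis=0)
    sd = cols.std(axis=0)  # population SD; 0 for n == 1
    return NetworkSummary(
        maxH=mx[0], meanH=mean[0], sdH=sd[0],
        maxA=mx[1], meanA=mean[1], sdA=sd[1],
        maxMC=mx[2], meanMC=mean[2], sdMC=sd[2],
        meanD=mean[3], sdD=sd[3],
        meanE=mean[4], sdE=sd[4],
        meanCD=mean[5], sdCD=sd[5],
    )


def build_profile(
    article: ArticleRecord,
    vocab: MeshVocabulary,
    edges: Iterable[CitationEdge],
    *,
    window_years: float | None = None,
    as_of_year: int | None = None,
    citing_articles: Mapping[str, ArticleRecord] | None = None,
    citing_scores: Mapping[str, tuple[HamcScore, CategoryFlags]] | None = None,
    exclude_clinical: bool = False,
    clinical_ids: set[str] | None = None,
    strict: bool = True,
    cpy_full_history: bool = False,
) -> DataProfile:
    """Compose one article's full 22-feature data profile.

    The citing articles' scores come either precomputed
    (``citing_scores``) or from ``citing_articles`` records scored against
    ``vocab``.  CPY uses the same window as the network summaries unless
    ``cpy_full_history`` overrides (then all edges count and the rate
    denominator runs to the latest citation year).
    """
    if window_years is None and as_of_year is None:
        window_years = math.inf
    score, flags = score_article(article, vocab)
    kept = restrict_network(
        edges,
        article,
        window_years=window_years,
        as_of_year=as_of_year,
        exclude_clinical=exclude_clinical,
        clinical_ids=clinical_ids,
    )

    citers: list[tuple[HamcScore, CategoryFlags]] = []
    for edge in kept:
        pair = None
        if citing_scores is not None:
            pair = citing_scores.get(edge.citing_id)
        elif citing_articles is not None and edge.citing_id in citing_articles:
            pair = score_article(citing_articles[edge.citing_id], vocab)
        if pair is None:
            if strict:
                raise KeyError(f"dangling citing_id {edge.citing_id!r}")
            continue
        citers.append(pair)

    if as_of_year is not None:
        rate_end = as_of_year
    elif math.isinf(window_years):
        rate_end = max((e.year for e in kept), default=article.pub_year)
    else:
        rate_end = article.pub_year + int(window_years)
    if cpy_full_history:
        all_edges = [e for e in edges if e.cited_id == article.article_id]
        rate_end = max((e.year for e in all_edges), default=article.pub_year)
        cpy = citation_rate(len(all_edges), article.pub_year, rate_end)
    else:
        cpy = citation_rate(len(citers) if strict else len(kept),
                            article.pub_year, rate_end)

    return DataProfile(
        h=score.h, a=score.a, mc=score.mc,
        d=flags.d, e=flags.e, cd=flags.cd,
        cpy=cpy,
        network=summarize_network(citers),
    )


# ---- corpus-scale (vectorised) profile building ---------------------------

def score_table(
    articles: Iterable[ArticleRecord], vocab: MeshVocabulary
) -> pd.DataFrame:
    """Per-article score table: h, a, mc, defined, d, e, cd, pub_year, clinical.

    Indexed by article_id; the tabular substrate for :func:`build_profiles`.
    """
    rows = {}
    for art in articles:
        s, f = score_article(art, vocab)
        rows[art.article_id] = (
            s.h, s.a, s.mc, s.defined, f.d, f.e, f.cd,
            art.pub_year, bool(art.is_clinical),
        )
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["h", "a", "mc", "defined", "d", "e", "cd",
                 "pub_year", "is_clinical"],
    ).rename_axis("article_id")


def build_profiles(
    scores: pd.DataFrame,
    edges: pd.DataFrame,
    *,
    window_years: float | None = None,
    as_of_year: int | None = None,
    exclude_clinical: bool = False,
) -> pd.DataFrame:
    """Build profiles for every article in ``scores`` at once.

    ``scores`` is a :func:`score_table` frame; ``edges`` has columns
    citing_id / cited_id / year.  Returns a frame indexed by article_id
    with the canonical 22 feature columns.  Same conventions as
    :func:`build_profile`; edges citing unknown articles raise KeyError.
    """
    if window_years is None and as_of_year is None:
        window_years = math.inf
    if (window_years is not None) and (as_of_year is not None):
        raise ValueError("give only one of window_years / as_of_year")

    ed = edges[["citing_id", "cited_id", "year"]].copy()
    unknown = ~ed["citing_id"].isin(scores.index)
    if unknown.any():
        raise KeyError(
            f"{int(unknown.sum())} edges cite unknown articles "
            f"(first: {ed.loc[unknown, 'citing_id'].iloc[0]!r})"
        )
    pub_year = scores["pub_year"]
    ed["pub_year"] = ed["cited_id"].map(pub_year)
    if as_of_year is not None:
        ed = ed[ed["year"] <= as_of_year]
        rate_end = pd.Series(as_of_year, index=scores.index)
    elif math.isinf(window_years):
        ed = ed[ed["year"] - ed["pub_year"] >= 0]  # keep all forward edges
        last = ed.groupby("cited_id")["year"].max()
        rate_end = last.reindex(scores.index).fillna(pub_year).astype(int)
    else:
        ed = ed[ed["year"] - ed["pub_year"] <= window_years]
        rate_end = pub_year + int(window_years)
    if exclude_clinical:
        clinical = scores.index[scores["is_clinical"]]
        ed = ed[~ed["citing_id"].isin(clinical)]

    citer = scores.loc[ed["citing_id"], ["h", "a", "mc", "d", "e", "cd"]]
    citer = citer.set_axis(ed.index).assign(cited_id=ed["cited_id"])
    grouped = citer.groupby("cited_id")

    agg = pd.DataFrame(index=scores.index)
    n = grouped.size().reindex(scores.index).fillna(0).astype(int)
    for col, label in (("h", "H"), ("a", "A"), ("mc", "MC")):
        agg[f"max{label}"] = grouped[col].max()
        agg[f"mean{label}"] = grouped[col].mean()
        agg[f"sd{label}"] = grouped[col].std(ddof=0)
    for col, label in (("d", "D"), ("e", "E"), ("cd", "CD")):
        agg[f"mean{label}"] = grouped[col].mean()
        agg[f"sd{label}"] = grouped[col].std(ddof=0)
    agg = agg.reindex(scores.index).fillna(0.0)

    elapsed = (rate_end - pub_year + 1).clip(lower=1)
    cpy = (n / elapsed).where(n > 0, 0.0)

    out = pd.DataFrame(index=scores.index)
    out["H"] = scores["h"]
    out["A"] = scores["a"]
    out["MC"] = scores["mc"]
    out["D"] = scores["d"].astype(float)
    out["E"] = scores["e"].astype(float)
    out["CD"] = scores["cd"].astype(float)
    out["CPY"] = cpy
    for name in NETWORK_FEATURES:
        out[name] = agg[name]
    assert tuple(out.columns) == FEATURE_NAMES
    return out


# ---- TSV I/O ---------------------------------------------------------------

def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"citing_id": str, "cited_id": str})
    expected = {"citing_id", "cited_id", "year"}
    if not expected.issubset(df.columns):
        raise ValueError(f"edge file must have columns {sorted(expected)}")
    return df[["citing_id", "cited_id", "year"]]


def write_edges_tsv(edges: pd.DataFrame | Iterable[CitationEdge],
                    path: str | Path) -> None:
    if not isinstance(edges, pd.DataFrame):
        edges = pd.DataFrame(
            [(e.citing_id, e.cited_id, e.year) for e in edges],
            columns=["citing_id", "cited_id", "year"],
        )
    edges.to_csv(path, sep="\t", index=False)


def write_profiles_tsv(
    profiles: pd.DataFrame,
    path: str | Path,
    labels: pd.Series | None = None,
) -> None:
    """Profiles (+ optional binary label column) with the canonical header."""
    df = profiles.copy()
    if labels is not None:
        df["label"] = labels.reindex(df.index).astype(int)
    df.rename_axis("article_id").to_csv(path, sep="\t")


def read_profiles_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(path, sep="\t", index_col="article_id")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").astype(int)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"profile file missing features: {sorted(missing)}")
    return df[list(FEATURE_NAMES)], labels
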