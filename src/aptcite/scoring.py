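"""HAMC content scoring and the triangle of biomedicine.

An article's Human / Animal / Molecular-Cellular term counts are converted
to *fractional* scores — each count divided by the total across the three
categories — which are barycentric coordinates on a 2-simplex.  The simplex
embeds in the plane as an equilateral triangle with vertices

    Human      (0, 1)
    Animal     (√3/2, −1/2)
    Mol./Cell. (−√3/2, −1/2)

so that human-focused work plots at the top and fundamental work along the
bottom edge.  Binary (presence/absence) counting is kept as a comparison
baseline; fractional counting separates articles that binary counting would
stack on the same point.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .mesh import (
    ArticleRecord,
    Category,
    MeshVocabulary,
    MODIFIER_CATEGORIES,
    category_counts,
)

__all__ = [
    "HamcScore",
    "CategoryFlags",
    "TriCoordinate",
    "ArticleFocus",
    "HumanBand",
    "fractional_hamc",
    "binary_hamc",
    "modifier_flags",
    "trilinear_coords",
    "article_focus",
    "human_fraction_band",
    "cumulative_clinical_curve",
    "score_article",
    "write_coordinates_tsv",
    "write_curve_tsv",
    "SQRT3_2",
]

SQRT3_2 = math.sqrt(3.0) / 2.0

#: planar coordinates of the triangle vertices, in (H, A, MC) order
TRIANGLE_VERTICES = ((0.0, 1.0), (SQRT3_2, -0.5), (-SQRT3_2, -0.5))

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class HamcScore:
    """Fractional Human/Animal/MolCell content of one article.

    ``defined`` is False for articles with zero HAMC terms; such articles
    have no position on the triangle and all fractions are 0.
    """

    h: float
    a: float
    mc: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined:
            total = self.h + self.a + self.mc
            if abs(total - 1.0) > _SIMPLEX_TOL:
                raise ValueError(f"HAMC fractions sum to {total}, not 1")
        elif self.h or self.a or self.mc:
            raise ValueError("undefined HamcScore must have zero fractions")


@dataclass(frozen=True)
class CategoryFlags:
    """Binary Disease / Therapeutic-Diagnostic / Chemical-Drug modifiers."""

    d: int
    e: int
    cd: int

    def __post_init__(self) -> None:
        for name in ("d", "e", "cd"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"flag {name} must be 0 or 1")


@dataclass(frozen=True)
class TriCoordinate:
    x: float
    y: float


class ArticleFocus(Enum):
    FUNDAMENTAL = "fundamental"        # animal/molcell terms, no human
    HUMAN_FOCUSED = "human_focused"    # human terms only
    MIXED = "mixed"
    UNCLASSIFIED = "unclassified"      # no HAMC terms at all


class HumanBand(Enum):
    """Tertile band of the human fraction, for intermediate articles."""

    LOW = "low"    # h ≤ 1/3
    MID = "mid"    # 1/3 < h ≤ 2/3
    HIGH = "high"  # h > 2/3


def _hamc_counts(counts: Mapping[Category, int]) -> tuple[int, int, int]:
    trio = (
        counts.get(Category.HUMAN, 0),
        counts.get(Category.ANIMAL, 0),
        counts.get(Category.MOLCELL, 0),
    )
    if any(c < 0 for c in trio):
        raise ValueError("category counts must be non-negative")
    return trio


def fractional_hamc(counts: Mapping[Category, int]) -> HamcScore:
    """Fractional counting: each HAMC count over the three-category total."""
    h, a, mc = _hamc_counts(counts)
    total = h + a + mc
    if total == 0:
        return HamcScore(0.0, 0.0, 0.0, defined=False)
    return HamcScore(h / total, a / total, mc / total)


def binary_hamc(counts: Mapping[Category, int]) -> HamcScore:
    """Binary counting baseline: presence/absence, normalised."""
    present = [int(c > 0) for c in _hamc_counts(counts)]
    total = sum(present)
    if total == 0:
        return HamcScore(0.0, 0.0, 0.0, defined=False)
    h, a, mc = (p / total for p in present)
    return HamcScore(h, a, mc)


def modifier_flags(counts: Mapping[Category, int]) -> CategoryFlags:
    """D/E/CD flags: 1 iff the article has ≥1 term in that category."""
    d, e, cd = (int(counts.get(cat, 0) > 0) for cat in MODIFIER_CATEGORIES)
    return CategoryFlags(d=d, e=e, cd=cd)


def trilinear_coords(score: HamcScore) -> TriCoordinate:
    """Map a defined HAMC score onto the triangle of biomedicine.

        x = H·0 + A·(√3/2) + MC·(−√3/2)
        y = H·1 + A·(−1/2) + MC·(−1/2)

    The constants are the vertex coordinates; the map is the barycentric
    interpolation of those vertices and therefore affine on the simplex.
    """
    if not score.defined:
        raise ValueError("article has no HAMC terms; no triangle position")
    x = score.a * SQRT3_2 - score.mc * SQRT3_2
    y = score.h - 0.5 * score.a - 0.5 * score.mc
    return TriCoordinate(x, y)


def article_focus(counts: Mapping[Category, int]) -> ArticleFocus:
    """Fundamental / human-focused / mixed classification from HAMC counts.

    Fundamental: ≥1 Animal or Mol/Cell term and no Human terms.
    Human-focused: ≥1 Human term and no Animal or Mol/Cell terms.
    """
    h, a, mc = _hamc_counts(counts)
    if h == 0 and (a > 0 or mc > 0):
        return ArticleFocus.FUNDAMENTAL
    if h > 0 and a == 0 and mc == 0:
        return ArticleFocus.HUMAN_FOCUSED
    if h == a == mc == 0:
        return ArticleFocus.UNCLASSIFIED
    return ArticleFocus.MIXED


def human_fraction_band(score: HamcScore) -> HumanBand:
    """Low/mid/high human-fraction band for intermediate articles.

    Defined only for 0 < h < 1 (pure-human and zero-human articles belong
    to the vertex/edge groups, not the intermediate bands).  Boundaries are
    inclusive on the left band: h ≤ 1/3 is LOW, 1/3 < h ≤ 2/3 MID.
    """
    if not score.defined or not 0.0 < score.h < 1.0:
        raise ValueError("human-fraction bands apply only to 0 < h < 1")
    if score.h <= 1.0 / 3.0:
        return HumanBand.LOW
    if score.h <= 2.0 / 3.0:
        return HumanBand.MID
    return HumanBand.HIGH


def score_article(
    article: ArticleRecord, vocab: MeshVocabulary
) -> tuple[HamcScore, CategoryFlags]:
    """Fractional HAMC score and D/E/CD flags of one article."""
    counts = category_counts(article, vocab)
    return fractional_hamc(counts), modifier_flags(counts)


def cumulative_clinical_curve(
    articles: Iterable[ArticleRecord],
    clinical_citation_years: Mapping[str, Sequence[int]],
    horizon_years: int,
    *,
    require_any_citation: bool = False,
    any_citation_ids: set[str] | None = None,
) -> list[tuple[int, float]]:
    """Cumulative proportion of a group ever cited by a clinical article.

    ``clinical_citation_years`` maps article id → years of its clinical
    citations (possibly empty).  For each t = 1..horizon the curve reports
    the fraction of group articles whose *first* clinical citation fell
    within t calendar years of publication (citation_year − pub_year ≤ t).
    Monotone non-decreasing by construction.

    ``require_any_citation`` restricts the denominator to articles with at
    least one citation of any kind (ids given in ``any_citation_ids``);
    both denominators are reported in the literature, so both are exposed.
    """
    if horizon_years < 1:
        raise ValueError("horizon must be ≥ 1 year")
    group = list(articles)
    if require_any_citation:
        if any_citation_ids is None:
            raise ValueError("require_any_citation needs any_citation_ids")
        group = [a for a in group if a.article_id in any_citation_ids]
    if not group:
        raise ValueError("empty article group")

    first_offset: list[float] = []
    for art in group:
        years = clinical_citation_years.get(art.article_id, ())
        first_offset.append(
            min((y - art.pub_year for y in years), default=math.inf)
        )
    n = len(group)
    return [
        (t, sum(off <= t for off in first_offset) / n)
        for t in range(1, horizon_years + 1)
    ]


# ---- TSV export ------------------------------------------------------------

def write_coordinates_tsv(
    rows: Iterable[tuple[str, HamcScore]], path: str | Path
) -> None:
    """Export (article_id, h, a, mc, x, y); undefined scores are skipped."""
    lines = ["article_id\th\ta\tmc\tx\ty"]
    for article_id, score in rows:
        if not score.defined:
            continue
        c = trilinear_coords(score)
        lines.append(
            f"{article_id}\t{score.h:.10g}\t{score.a:.10g}\t{score.mc:.10g}"
            f"\t{c.x:.10g}\t{c.y:.10g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_curve_tsv(curve: Sequence[tuple[int, float]], path: str | Path) -> None:
    lines = ["t_years\tproportion"]
    lines += [f"{t}\t{p:.10g}" for t, p in curve]
    Path(path).write_text("\n".join(lines) + "\n")
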