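"""Seeded synthetic literature corpora with a known clinical-citation mechanism.

Every downstream component — content scoring, data profiles, the APT
classifier, citation editing — is exercised against corpora generated here,
so nothing in the test suite depends on bulk downloads.  The generator
emulates three things:

* **content** — each article draws a Human/Animal/Mol-Cell composition from
  a Dirichlet mixture whose components mirror the populations of the
  triangle of biomedicine: molecular/cellular fundamental work, animal-model
  work (which in real literatures co-occurs with human disease content:
  in-vivo models sit mid-way on the bench-to-bedside path and carry the
  Disease terms of the conditions they model), mixed
  translational work, and human clinical work.  Compositions become actual
  MeSH descriptor lists drawn from a packaged miniature vocabulary, so the
  classification stack runs for real;
* **citation dynamics** — the network grows year by year; a new article
  cites earlier ones with probability proportional to
  ``(1 + prior citations)^α × exp(−d/width)`` where ``d`` is the Euclidean
  distance between the two articles on the triangle (preferential
  attachment damped by content similarity);
* **outcome** — each article's probability of eventual clinical citation is
  a logistic function of its realised citing network,
  ``σ(β0 + β_meanH·meanH + β_meanA·meanA + β_cpy·log1p(CPY) + β_meanD·meanD)``,
  and the
  binary label is a Bernoulli draw from it.  Because the generative
  probability is recorded, the Bayes AUC — the discrimination ceiling any
  classifier can approach — is computable exactly.

What this does *not* emulate: field sizes, journals, author effects, term
drift, or any real-data missingness; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .mesh import ArticleRecord, Category, MeshVocabulary
from .scoring import SQRT3_2

__all__ = [
    "CorpusConfig",
    "SyntheticCorpus",
    "fixture_vocabulary",
    "generate",
    "bayes_auc",
]


# ---- miniature fixture vocabulary -----------------------------------------

#: descriptor name → tree addresses, spanning all six category systems plus
#: the carve-outs (C22, E07) and no-category branches.  Names are plausible
#: biomedical descriptors; addresses follow the real branch layout.
_FIXTURE_ITEMS: dict[str, tuple[str, ...]] = {
    # Human: the Humans address plus the Persons (M01) branch
    "Humans": ("B01.050.150.900.649.801.400.112.400.400",),
    "Adult": ("M01.060.116",),
    "Child": ("M01.060.406",),
    "Adolescent": ("M01.060.057",),
    "Aged": ("M01.060.116.100",),
    "Patients": ("M01.643",),
    "Pregnant Women": ("M01.975",),
    "Health Personnel": ("M01.526",),
    "Survivors": ("M01.937",),
    # Animal: B01 minus the Humans address
    "Animals": ("B01.050",),
    "Mice": ("B01.050.150.900.649.313.992.635.505.500",),
    "Rats": ("B01.050.150.900.649.313.992.635.505.700",),
    "Mice, Knockout": ("B01.050.150.900.649.313.992.635.505.500.400",),
    "Zebrafish": ("B01.050.150.700.300.995",),
    "Dogs": ("B01.050.150.900.649.313.750.200",),
    "Rabbits": ("B01.050.150.900.649.313.988.400.112.199",),
    "Swine": ("B01.050.150.900.649.313.750.850",),
    "Drosophila melanogaster": ("B01.050.500.131.365.249.300",),
    # Molecular/Cellular: A11, B02–B04, G02.111.570, G02.149
    "Cell Line": ("A11.251.210",),
    "Cells, Cultured": ("A11.251",),
    "HeLa Cells": ("A11.251.210.505",),
    "Fibroblasts": ("A11.329.228",),
    "Stem Cells": ("A11.872",),
    "Escherichia coli": ("B03.440.450.425.325.300",),
    "Archaea": ("B02.075",),
    "Bacteriophages": ("B04.123",),
    "Protein Conformation": ("G02.111.570.820",),
    "Phosphorylation": ("G02.149.633",),
    # Disease (C branch, excluding C22 animal diseases)
    "Neoplasms": ("C04",),
    "Breast Neoplasms": ("C04.588.180",),
    "Diabetes Mellitus": ("C18.452.394.750",),
    "Cardiovascular Diseases": ("C14",),
    "Hypertension": ("C14.907.489",),
    "Alzheimer Disease": ("C10.228.140.380.100",),
    "Asthma": ("C08.127.108",),
    "Stroke": ("C10.228.140.300.775",),
    # C22: animal diseases — on the C branch but NOT Disease by the rule
    "Rodent Diseases": ("C22.795",),
    "Dog Diseases": ("C22.268",),
    # Therapeutic/Diagnostic (E branch, excluding E07 equipment)
    "Drug Therapy": ("E02.319",),
    "Surgical Procedures, Operative": ("E04",),
    "Immunotherapy": ("E02.095.465",),
    "Magnetic Resonance Imaging": ("E01.370.350.825.500",),
    "Radiotherapy": ("E02.815",),
    "Mass Screening": ("E01.370.500.580",),
    # E07: equipment and supplies — excluded from Therapeutic
    "Surgical Instruments": ("E07.858",),
    # Chemical/Drug (D branch)
    "Antineoplastic Agents": ("D27.505.954.248",),
    "Proteins": ("D12.776",),
    "Antibodies, Monoclonal": ("D12.776.124.486.485.114.224",),
    "DNA": ("D13.444.308",),
    "Anti-Bacterial Agents": ("D27.505.954.122.085",),
    "Insulin": ("D06.472.699.587.200",),
    # multi-category and no-category descriptors
    "Disease Models, Animal": ("E05.598.500", "B01.050.199"),  # Therap + Animal
    "Tumor Cells, Cultured": ("A11.251.860", "C04.557.470"),   # MolCell + Disease
    "United States": ("Z01.107.567.875",),
    "Risk Factors": ("N06.850.520.830.600",),
    "History, 20th Century": ("K01.400.504.968",),
}


def fixture_vocabulary(*, strict: bool = True) -> MeshVocabulary:
    """The packaged miniature MeSH vocabulary (~54 descriptors)."""
    return MeshVocabulary.from_items(_FIXTURE_ITEMS, strict=strict)


#: single-category descriptor pools the generator samples from
_POOLS: dict[Category, tuple[str, ...]] = {
    Category.HUMAN: ("Humans", "Adult", "Child", "Adolescent", "Aged",
                     "Patients", "Pregnant Women", "Health Personnel",
                     "Survivors"),
    Category.ANIMAL: ("Animals", "Mice", "Rats", "Mice, Knockout",
                      "Zebrafish", "Dogs", "Rabbits", "Swine",
                      "Drosophila melanogaster"),
    Category.MOLCELL: ("Cell Line", "Cells, Cultured", "HeLa Cells",
                       "Fibroblasts", "Stem Cells", "Escherichia coli",
                       "Archaea", "Bacteriophages", "Protein Conformation",
                       "Phosphorylation"),
    Category.DISEASE: ("Neoplasms", "Breast Neoplasms", "Diabetes Mellitus",
                       "Cardiovascular Diseases", "Hypertension",
                       "Alzheimer Disease", "Asthma", "Stroke"),
    Category.THERAP: ("Drug Therapy", "Surgical Procedures, Operative",
                      "Immunotherapy", "Magnetic Resonance Imaging",
                      "Radiotherapy", "Mass Screening"),
    Category.CHEMDRUG: ("Antineoplastic Agents", "Proteins",
                        "Antibodies, Monoclonal", "DNA",
                        "Anti-Bacterial Agents", "Insulin"),
}


# ---- configuration ---------------------------------------------------------

@dataclass(frozen=True)
class CorpusConfig:
    """Generator parameters; the defaults are the package's study conditions.

    The content mixture places articles in four triangle populations
    (weights, then Dirichlet concentrations over H/A/MC); flag
    probabilities are affine in the composition (human content for all
    three; animal content additionally for Disease); the citation process
    combines preferential attachment (exponent ``pa_exponent``) with a
    content-similarity kernel ``exp(−d/similarity_width)``; the outcome
    is logistic in (meanH of citers, log1p CPY, meanD of citers).  The
    default coefficients put the clinical-citation prevalence in the
    0.2–0.3 band typical of mature literature corpora.
    """

    n_articles: int = 10_000
    year_range: tuple[int, int] = (1995, 2010)
    seed: int = 0
    # content
    mixture_weights: tuple[float, ...] = (0.30, 0.25, 0.20, 0.25)
    mixture_alphas: tuple[tuple[float, float, float], ...] = (
        (0.4, 0.8, 6.0),   # molecular/cellular fundamental
        (1.5, 5.0, 1.0),   # animal-model (co-occurring human content)
        (3.0, 3.0, 1.5),   # translational mixed
        (6.0, 1.0, 0.4),   # human clinical
    )
    term_count_mean: float = 4.0     # mean HAMC terms per article (min 1)
    # P(flag) = intercept + slope_h·h + slope_a·a, clipped to [0, 1].
    # Disease terms load on animal content as well as human content:
    # an in-vivo disease model is indexed under the disease it models.
    flag_probs: dict = field(default_factory=lambda: {
        "d": (0.20, 0.45, 0.35),
        "e": (0.15, 0.55, 0.15),
        "cd": (0.35, 0.20, 0.0),
    })
    clinical_base: float = 0.02      # P(clinical citer) = base + slope·h
    clinical_slope: float = 0.25
    # citation dynamics
    citation_rate: float = 6.0       # mean references per citing article
    pa_exponent: float = 0.8         # preferential-attachment exponent α
    similarity_width: float = 0.7    # kernel width on triangle distance
    similarity_on: bool = True
    # outcome (logit scale); animal content carries real translational
    # signal of its own (below the human weight, above none): without it
    # the A and MC axes would be exchangeable by the simplex identity and
    # no citing-network experiment could order them
    beta0: float = -2.75
    beta_mean_h: float = 2.2
    beta_mean_a: float = 0.9
    beta_cpy: float = 1.0
    beta_mean_d: float = 0.8

    def __post_init__(self) -> None:
        if self.n_articles < 10:
            raise ValueError("n_articles must be ≥ 10")
        if self.year_range[1] <= self.year_range[0]:
            raise ValueError("year_range must span ≥ 2 years")
        if len(self.mixture_weights) != len(self.mixture_alphas):
            raise ValueError("one Dirichlet concentration per mixture weight")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for name in ("clinical_base", "clinical_slope"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} out of [0, 1]")
        if self.citation_rate < 0:
            raise ValueError("citation_rate must be ≥ 0")
        if self.citation_rate == 0 and self.beta_cpy != 0:
            raise ValueError(
                "zero citation rate cannot support a CPY outcome effect"
            )


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its generative ground truth.

    ``truth`` is a per-article frame (h, a, mc, d, e, cd, pub_year,
    is_clinical) identical to what scoring the articles against the
    fixture vocabulary produces — a property the tests verify — plus the
    mechanism columns mean_h_citers, mean_d_citers, cpy_true, true_prob.
    """

    config: CorpusConfig
    articles: list[ArticleRecord]
    edges: pd.DataFrame                     # citing_id, cited_id, year (sorted)
    truth: pd.DataFrame
    vocab: MeshVocabulary

    @property
    def labels(self) -> pd.Series:
        return self.truth["label"]

    @property
    def true_prob(self) -> pd.Series:
        return self.truth["true_prob"]

    def score_table(self) -> pd.DataFrame:
        """The score-table view consumed by profile building."""
        return self.truth[["h", "a", "mc", "defined", "d", "e", "cd",
                           "pub_year", "is_clinical"]].copy()

    def clinical_citation_years(self) -> dict[str, list[int]]:
        """Article id → years of clinical citations (for curve plotting)."""
        clin = set(self.truth.index[self.truth["is_clinical"]])
        ed = self.edges[self.edges["citing_id"].isin(clin)]
        return {k: sorted(v) for k, v in
                ed.groupby("cited_id")["year"].apply(list).items()}

    def write(self, directory: str | Path) -> None:
        """Emit the JSON-lines / TSV artifacts the file readers consume."""
        from .mesh import write_articles_jsonl
        from .profiles import write_edges_tsv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_articles_jsonl(self.articles, directory / "articles.jsonl")
        write_edges_tsv(self.edges, directory / "edges.tsv")
        self.vocab.to_tsv(directory / "vocabulary.tsv")
        self.truth.rename_axis("article_id").to_csv(
            directory / "truth.tsv", sep="\t"
        )


# ---- generation ------------------------------------------------------------

def _draw_terms(
    rng: np.random.Generator,
    counts: tuple[int, int, int],
    flags: tuple[int, int, int],
) -> tuple[list[str], tuple[int, int, int]]:
    """Descriptor list realising the requested per-category counts.

    Counts are capped at pool size (the realised counts are returned);
    each flagged modifier category contributes one descriptor.
    """
    terms: list[str] = []
    realised = []
    for cat, want in zip((Category.HUMAN, Category.ANIMAL, Category.MOLCELL),
                         counts):
        pool = _POOLS[cat]
        k = min(want, len(pool))
        realised.append(k)
        if k:
            idx = rng.choice(len(pool), size=k, replace=False)
            terms += [pool[i] for i in idx]
    for cat, flag in zip((Category.DISEASE, Category.THERAP,
                          Category.CHEMDRUG), flags):
        if flag:
            pool = _POOLS[cat]
            terms.append(pool[int(rng.integers(len(pool)))])
    return terms, tuple(realised)


def generate(config: CorpusConfig) -> SyntheticCorpus:
    """Generate a corpus; byte-identical for identical configs."""
    master = np.random.default_rng(config.seed)
    rng_content, rng_network, rng_outcome = master.spawn(3)
    n = config.n_articles
    y0, y1 = config.year_range
    vocab = fixture_vocabulary()

    # --- content -----------------------------------------------------------
    years = np.sort(rng_content.integers(y0, y1 + 1, size=n))
    comp_idx = rng_content.choice(
        len(config.mixture_weights), size=n, p=config.mixture_weights
    )
    alphas = np.array(config.mixture_alphas)
    comps = np.empty((n, 3))
    for j in range(len(config.mixture_weights)):
        mask = comp_idx == j
        comps[mask] = rng_content.dirichlet(alphas[j], size=int(mask.sum()))

    totals = 1 + rng_content.poisson(max(config.term_count_mean - 1.0, 0.0),
                                     size=n)
    raw_counts = np.array(
        [rng_content.multinomial(t, p) for t, p in zip(totals, comps)]
    )
    # flag and clinical probabilities follow the intended composition;
    # realised h is recomputed from the drawn counts below
    hcoef, acoef = comps[:, 0], comps[:, 1]
    flag_draws = {}
    for name, (icept, slope_h, slope_a) in config.flag_probs.items():
        p = np.clip(icept + slope_h * hcoef + slope_a * acoef, 0.0, 1.0)
        flag_draws[name] = (rng_content.random(n) < p).astype(int)
    p_clin = np.clip(config.clinical_base + config.clinical_slope * hcoef,
                     0.0, 1.0)
    is_clinical = rng_content.random(n) < p_clin

    articles: list[ArticleRecord] = []
    ids = np.array([f"A{i:07d}" for i in range(n)])
    counts = np.empty((n, 3), dtype=int)
    for i in range(n):
        flags = (flag_draws["d"][i], flag_draws["e"][i], flag_draws["cd"][i])
        terms, realised = _draw_terms(rng_content, tuple(raw_counts[i]), flags)
        counts[i] = realised
        pub_types = ["journal article"]
        if is_clinical[i]:
            pub_types.append("clinical trial")
        articles.append(ArticleRecord(
            article_id=str(ids[i]), pub_year=int(years[i]),
            mesh_terms=terms, pub_types=pub_types,
        ))
    hamc_total = counts.sum(axis=1)
    # totals ≥ 1 and pools are larger than typical draws, but a capped draw
    # can in principle zero out; guard the division
    safe = np.maximum(hamc_total, 1)
    h = counts[:, 0] / safe
    a = counts[:, 1] / safe
    mc = counts[:, 2] / safe
    defined = hamc_total > 0
    tri_x = (a - mc) * SQRT3_2
    tri_y = h - 0.5 * (a + mc)

    # --- citation dynamics -------------------------------------------------
    edges_citing: list[np.ndarray] = []
    edges_cited: list[np.ndarray] = []
    edges_year: list[np.ndarray] = []
    indeg = np.zeros(n)
    year_starts = np.searchsorted(years, np.arange(y0, y1 + 2))
    for yi, year in enumerate(range(y0 + 1, y1 + 1)):
        n_prior = year_starts[year - y0]      # articles published before `year`
        lo, hi = year_starts[year - y0], year_starts[year - y0 + 1]
        n_new = hi - lo
        if n_prior == 0 or n_new == 0:
            continue
        k_out = rng_network.poisson(config.citation_rate, size=n_new)
        total = int(k_out.sum())
        if total == 0:
            continue
        weights = (1.0 + indeg[:n_prior]) ** config.pa_exponent
        cumw = np.cumsum(weights)
        citing_pos = np.repeat(np.arange(lo, hi), k_out)
        targets = np.empty(total, dtype=int)
        pending = np.arange(total)
        for _ in range(200):
            u = rng_network.random(len(pending)) * cumw[-1]
            prop = np.searchsorted(cumw, u)
            if config.similarity_on:
                dx = tri_x[citing_pos[pending]] - tri_x[prop]
                dy = tri_y[citing_pos[pending]] - tri_y[prop]
                accept_p = np.exp(-np.hypot(dx, dy) / config.similarity_width)
                ok = rng_network.random(len(pending)) < accept_p
            else:
                ok = np.ones(len(pending), dtype=bool)
            targets[pending[ok]] = prop[ok]
            pending = pending[~ok]
            if len(pending) == 0:
                break
        else:  # pragma: no cover - vanishing probability
            u = rng_network.random(len(pending)) * cumw[-1]
            targets[pending] = np.searchsorted(cumw, u)
        # one citation per (citing, cited) pair
        pairs = pd.DataFrame({"citing": citing_pos, "cited": targets})
        pairs = pairs.drop_duplicates()
        np.add.at(indeg, pairs["cited"].to_numpy(), 1.0)
        edges_citing.append(pairs["citing"].to_numpy())
        edges_cited.append(pairs["cited"].to_numpy())
        edges_year.append(np.full(len(pairs), year))

    if edges_citing:
        citing_all = np.concatenate(edges_citing)
        cited_all = np.concatenate(edges_cited)
        year_all = np.concatenate(edges_year)
    else:
        citing_all = cited_all = year_all = np.empty(0, dtype=int)
    edges = pd.DataFrame({
        "citing_id": ids[citing_all],
        "cited_id": ids[cited_all],
        "year": year_all.astype(int),
    })

    # --- outcome mechanism -------------------------------------------------
    n_cit = np.zeros(n)
    sum_h = np.zeros(n)
    sum_a = np.zeros(n)
    sum_d = np.zeros(n)
    np.add.at(n_cit, cited_all, 1.0)
    np.add.at(sum_h, cited_all, h[citing_all])
    np.add.at(sum_a, cited_all, a[citing_all])
    np.add.at(sum_d, cited_all, flag_draws["d"][citing_all].astype(float))
    with np.errstate(invalid="ignore"):
        mean_h = np.where(n_cit > 0, sum_h / np.maximum(n_cit, 1), 0.0)
        mean_a = np.where(n_cit > 0, sum_a / np.maximum(n_cit, 1), 0.0)
        mean_d = np.where(n_cit > 0, sum_d / np.maximum(n_cit, 1), 0.0)
    cpy = n_cit / (y1 - years + 1)
    logit = (config.beta0
             + config.beta_mean_h * mean_h
             + config.beta_mean_a * mean_a
             + config.beta_cpy * np.log1p(cpy)
             + config.beta_mean_d * mean_d)
    true_prob = expit(logit)
    label = (rng_outcome.random(n) < true_prob).astype(int)

    truth = pd.DataFrame({
        "h": h, "a": a, "mc": mc, "defined": defined,
        "d": flag_draws["d"], "e": flag_draws["e"], "cd": flag_draws["cd"],
        "pub_year": years, "is_clinical": is_clinical,
        "mean_h_citers": mean_h, "mean_a_citers": mean_a,
        "mean_d_citers": mean_d, "cpy_true": cpy,
        "true_prob": true_prob, "label": label,
    }, index=pd.Index(ids, name="article_id"))

    return SyntheticCorpus(
        config=config, articles=articles, edges=edges, truth=truth,
        vocab=vocab,
    )


def bayes_auc(corpus: SyntheticCorpus) -> float:
    """AUC of the true generative probabilities against the realised labels.

    No classifier trained on the profiles can systematically beat this
    ceiling; 0.5 for a constant-probability corpus.
    """
    labels = corpus.labels.to_numpy()
    prob = corpus.true_prob.to_numpy()
    if len(np.unique(prob)) == 1 or len(np.unique(labels)) == 1:
        return 0.5
    return float(roc_auc_score(labels, prob))
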