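"""Data-profile construction: windows, citation rate, network summaries."""

import math

import numpy as np
import pandas as pd
import pytest

import aptcite as ac
from aptcite.profiles import (
    ARTICLE_FEATURES,
    FEATURE_NAMES,
    NETWORK_FEATURES,
    build_profiles,
    score_table,
)
from aptcite.scoring import CategoryFlags, HamcScore

E = ac.CitationEdge


@pytest.fixture()
def article():
    return ac.ArticleRecord("tgt", 2000, mesh_terms=["Humans"])


# ---- restrict_network ------------------------------------------------------

def test_window_is_inclusive(article):
    edges = [E(f"c{o}", "tgt", 2000 + o) for o in (0, 1, 2, 3)]
    kept = ac.restrict_network(edges, article, window_years=2)
    assert {e.year for e in kept} == {2000, 2001, 2002}


def test_window_infinite_is_identity(article):
    edges = [E("c1", "tgt", 2001), E("c2", "tgt", 2030)]
    assert ac.restrict_network(edges, article, window_years=math.inf) == edges


def test_exclude_clinical_citers(article):
    edges = [E("c1", "tgt", 2001), E("c2", "tgt", 2001)]
    kept = ac.restrict_network(edges, article, window_years=5,
                               exclude_clinical=True,
                               clinical_ids={"c1", "c2"})
    assert kept == []


def test_windows_are_monotone(article):
    edges = [E(f"c{i}", "tgt", 2000 + i) for i in range(8)]
    prev: set = set()
    for w in (0, 2, 5, 7):
        kept = {e.citing_id for e in
                ac.restrict_network(edges, article, window_years=w)}
        assert prev <= kept
        prev = kept


# ---- citation rate ---------------------------------------------------------

@pytest.mark.parametrize(
    "n,pub,as_of,expected",
    [
        (10, 2000, 2001, 5.0),   # two elapsed calendar years
        (0, 2000, 2010, 0.0),
        (5, 2000, 2000, 5.0),    # publication-year floor
        (6, 2000, 2002, 2.0),
    ],
)
def test_citation_rate(n, pub, as_of, expected):
    assert ac.citation_rate(n, pub, as_of) == expected


def test_citation_rate_rejects_backwards_window():
    with pytest.raises(ValueError):
        ac.citation_rate(1, 2005, 2004)


# ---- summarize_network -----------------------------------------------------

def _citer(h=0.0, a=0.0, mc=0.0, d=0, e=0, cd=0, defined=True):
    if not defined:
        return (HamcScore(0, 0, 0, defined=False), CategoryFlags(d, e, cd))
    return (HamcScore(h, a, mc), CategoryFlags(d, e, cd))


def test_summary_singleton():
    s = ac.summarize_network([_citer(h=1.0, d=1)])
    assert (s.maxH, s.meanH, s.sdH) == (1.0, 1.0, 0.0)
    assert (s.meanD, s.sdD) == (1.0, 0.0)
    assert (s.meanA, s.maxMC) == (0.0, 0.0)
    assert not s.is_empty


def test_summary_two_citers_population_sd():
    s = ac.summarize_network([_citer(h=1.0), _citer(mc=1.0)])
    assert s.meanH == 0.5 and s.maxH == 1.0
    assert s.sdH == pytest.approx(0.5)   # population SD, not sample SD


def test_summary_empty_network():
    s = ac.summarize_network([])
    assert s.is_empty and s.as_tuple() == (0.0,) * 15


def test_summary_undefined_citers_count_as_zeros():
    s = ac.summarize_network([_citer(h=1.0), _citer(a=1.0, d=1),
                              _citer(defined=False, d=1)])
    assert s.meanH == pytest.approx(1 / 3)
    assert s.meanD == pytest.approx(2 / 3)


def test_summary_brute_force_oracle():
    """max/mean/population-SD agree with direct numpy on random networks."""
    rng = np.random.default_rng(99)
    for _ in range(300):
        n = int(rng.integers(1, 12))
        comp = rng.dirichlet((1, 1, 1), size=n)
        flags = rng.integers(0, 2, size=(n, 3))
        citers = [
            _citer(*comp[i], *flags[i]) for i in range(n)
        ]
        s = ac.summarize_network(citers)
        cols = np.column_stack([comp, flags.astype(float)])
        assert s.maxH == pytest.approx(cols[:, 0].max())
        assert s.meanA == pytest.approx(cols[:, 1].mean())
        assert s.sdMC == pytest.approx(cols[:, 2].std())
        assert s.meanD == pytest.approx(cols[:, 3].mean())
        assert s.sdCD == pytest.approx(cols[:, 5].std())


# ---- build_profile ---------------------------------------------------------

def test_profile_flattens_to_22_canonical_features():
    assert len(FEATURE_NAMES) == 22
    assert len(ARTICLE_FEATURES) == 7 and len(NETWORK_FEATURES) == 15
    prof = ac.DataProfile(h=1, a=0, mc=0, d=0, e=0, cd=0, cpy=0.0)
    assert prof.flatten().shape == (22,)
    assert list(prof.as_series().index) == list(FEATURE_NAMES)


def test_profile_empty_network(vocab, article):
    prof = ac.build_profile(article, vocab, [], window_years=2,
                            citing_scores={})
    assert prof.cpy == 0.0 and prof.network.is_empty
    assert prof.h == 1.0


def test_profile_hand_computed_fixture(vocab):
    """Three-article fixture: profile equals the hand-derived vector."""
    target = ac.ArticleRecord("t", 2000,
                              mesh_terms=["Humans", "Mice", "Neoplasms"])
    c1 = ac.ArticleRecord("c1", 2001, mesh_terms=["Humans", "Drug Therapy"])
    c2 = ac.ArticleRecord("c2", 2002, mesh_terms=["Mice", "Cell Line"])
    edges = [E("c1", "t", 2001), E("c2", "t", 2002)]
    prof = ac.build_profile(
        target, vocab, edges, window_years=2,
        citing_articles={"c1": c1, "c2": c2},
    )
    # article: H=A=0.5, D flag set (Neoplasms), no E/CD
    assert (prof.h, prof.a, prof.mc) == (0.5, 0.5, 0.0)
    assert (prof.d, prof.e, prof.cd) == (1, 0, 0)
    # 2 citations over 2000-2002 → 2/3 per year
    assert prof.cpy == pytest.approx(2 / 3)
    # citers: (1,0,0,e=1) and (0,.5,.5)
    net = prof.network
    assert net.maxH == 1.0 and net.meanH == 0.5 and net.sdH == 0.5
    assert net.meanA == 0.25 and net.meanMC == 0.25
    assert net.meanE == 0.5 and net.sdE == 0.5
    assert net.meanD == 0.0


def test_profile_dangling_citer_strict_vs_lenient(vocab, article):
    edges = [E("ghost", "tgt", 2001)]
    with pytest.raises(KeyError):
        ac.build_profile(article, vocab, edges, window_years=5,
                         citing_scores={})
    prof = ac.build_profile(article, vocab, edges, window_years=5,
                            citing_scores={}, strict=False)
    assert prof.network.is_empty


def test_duplicate_citer_changes_rate_not_composition(vocab, article):
    citer = ac.ArticleRecord("c1", 2001, mesh_terms=["Humans"])
    base_edges = [E("c1", "tgt", 2001)]
    dup_edges = base_edges + [E("c1", "tgt", 2001)]
    kwargs = dict(window_years=2, citing_articles={"c1": citer})
    p1 = ac.build_profile(article, vocab, base_edges, **kwargs)
    p2 = ac.build_profile(article, vocab, dup_edges, **kwargs)
    assert p2.cpy == 2 * p1.cpy
    assert (p2.network.meanH, p2.network.sdH, p2.network.maxH) == \
           (p1.network.meanH, p1.network.sdH, p1.network.maxH)


# ---- vectorised corpus path ------------------------------------------------

def test_build_profiles_matches_single_article_path(small_corpus, vocab):
    scores = small_corpus.score_table()
    profs = build_profiles(scores, small_corpus.edges, window_years=3)

    by_id = {a.article_id: a for a in small_corpus.articles}
    edge_objs = [
        E(r.citing_id, r.cited_id, int(r.year))
        for r in small_corpus.edges.itertuples()
    ]
    rng = np.random.default_rng(1)
    sample = rng.choice(scores.index, size=25, replace=False)
    for aid in sample:
        single = ac.build_profile(
            by_id[aid], vocab,
            [e for e in edge_objs if e.cited_id == aid],
            window_years=3, citing_articles=by_id,
        )
        np.testing.assert_allclose(
            profs.loc[aid].to_numpy(), single.flatten(), atol=1e-12
        )


def test_score_table_matches_generator_truth(small_corpus, vocab):
    """Scoring the emitted MeSH terms recovers the generator's ground truth."""
    recomputed = score_table(small_corpus.articles, vocab)
    truth = small_corpus.score_table()
    pd.testing.assert_frame_equal(
        recomputed.sort_index(), truth.sort_index(), check_dtype=False
    )


def test_build_profiles_rejects_unknown_citers(small_corpus):
    scores = small_corpus.score_table()
    bad = pd.DataFrame(
        {"citing_id": ["nope"], "cited_id": [scores.index[0]], "year": [2001]}
    )
    with pytest.raises(KeyError):
        build_profiles(scores, bad)


def test_profiles_tsv_round_trip(tmp_path, small_corpus):
    scores = small_corpus.score_table()
    profs = build_profiles(scores, small_corpus.edges).head(50)
    labels = small_corpus.labels.head(50)
    p = tmp_path / "profiles.tsv"
    ac.write_profiles_tsv(profs, p, labels)
    back, back_labels = ac.read_profiles_tsv(p)
    np.testing.assert_allclose(back.to_numpy(), profs.to_numpy(), rtol=1e-9)
    assert (back_labels == labels).all()
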