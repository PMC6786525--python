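import numpy as np
import pytest

import aptcite as ac


@pytest.fixture(scope="session")
def vocab():
    return ac.fixture_vocabulary()


@pytest.fixture(scope="session")
def small_corpus():
    """A small but structurally complete corpus for module-level tests."""
    cfg = ac.CorpusConfig(n_articles=1500, year_range=(2000, 2008), seed=42)
    return ac.generate(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_corpus):
    scores = small_corpus.score_table()
    return ac.build_profiles(scores, small_corpus.edges)


@pytest.fixture(scope="session")
def trained_small(small_corpus, small_profiles):
    """Forest + calibration trained on the small corpus (shared, seeded)."""
    y = small_corpus.labels.to_numpy()
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(y))
    tr, cal = perm[:900], perm[900:]
    clf = ac.train(small_profiles.iloc[tr], y[tr], seed=5)
    raw = ac.predict_raw(clf, small_profiles.iloc[cal])
    calib = ac.calibrate_bins(raw, y[cal])
    return clf, calib
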