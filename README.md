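# aptcite

Predicting whether a biomedical research article will eventually be cited
by a clinical trial or guideline, from its MeSH content and the shape of
its citing network.

Most biomedical papers never directly touch clinical practice; the subset
that do are usually recognisable only in hindsight, decades later.
`aptcite` implements a pipeline that makes that recognition prospective:

1. **Content classification** (`aptcite.mesh`). Each MeSH descriptor is
   mapped to its tree address(es) and classified into six category systems:
   Human (the Humans descriptor or the M01 Persons branch), Animal (B01
   except Humans), Molecular/Cellular (A11, B02–B04, G02.111.570, G02.149),
   plus three binary modifiers — Disease (C except C22), Therapeutic/
   Diagnostic Approaches (E except E07), Chemical/Drug (D).
2. **The triangle of biomedicine** (`aptcite.scoring`). Fractional
   counting turns per-category term counts into simplex scores
   (H, A, MC), H + A + MC = 1, drawn as an equilateral triangle via

       x = A·(√3/2) − MC·(√3/2)
       y = H − (A + MC)/2

   with vertices Human (0, 1), Animal (√3/2, −½), Mol/Cell (−√3/2, −½).
3. **Data profiles** (`aptcite.profiles`). Each article becomes a
   22-feature vector: its own H, A, MC, D, E, CD and citation rate (CPY),
   plus max/mean/SD of the citing articles' H/A/MC scores and mean/SD of
   their D/E/CD flags — optionally truncated to the network visible a few
   years after publication.
4. **The APT score** (`aptcite.classifier`). A random forest (majority
   class downsampled 2:1) votes on whether the article will be clinically
   cited; the vote fraction is calibrated into five bins with empirical
   positive rates at <5%, 25%, 50%, 75% and >95% — the Approximate
   Potential to Translate.
5. **Citation editing** (`aptcite.editing`). Counterfactual surgery on a
   citing network — replacing newly acquired citations with homogeneous
   Human / Animal / Mol-Cell / Human-plus-flags citers, or with resampled
   copies of the old network — measures *what it is* about a growing
   network that moves APT scores.
6. **Synthetic corpora** (`aptcite.simulate`). A seeded generator plants
   a known logistic clinical-citation mechanism on a preferential-
   attachment, content-similarity citation network, so the whole pipeline
   is testable without bulk literature downloads, and the Bayes AUC
   ceiling is computable exactly.

## Worked example

```python
import numpy as np, aptcite as ac

cfg = ac.CorpusConfig(n_articles=10_000, year_range=(1995, 2010), seed=7)
corpus = ac.generate(cfg)
profiles = ac.build_profiles(corpus.score_table(), corpus.edges)
y = corpus.labels.to_numpy()
print(f"clinically cited prevalence: {y.mean():.3f}")
print(f"Bayes AUC ceiling: {ac.bayes_auc(corpus):.3f}")

rng = np.random.default_rng(0)
perm = rng.permutation(len(y))
tr, cal, te = perm[:5000], perm[5000:7000], perm[7000:]
clf = ac.train(profiles.iloc[tr], y[tr], seed=1)
calib = ac.calibrate_bins(ac.predict_raw(clf, profiles.iloc[cal]), y[cal])
res = ac.evaluate(clf, profiles.iloc[te], y[te])
print(f"held-out accuracy: {res['accuracy']:.3f}   F1: {res['f1']:.3f}   AUC: {res['auc']:.3f}")
print("per-bin positive rates:", [round(r, 3) for r in calib.bin_rates])
```

prints

```
clinically cited prevalence: 0.212
Bayes AUC ceiling: 0.780
held-out accuracy: 0.741   F1: 0.453   AUC: 0.746
per-bin positive rates: [0.052, 0.253, 0.5, 0.75, 1.0]
```

About 21% of the synthetic articles are eventually cited by a clinical
article. The planted mechanism caps discrimination at AUC 0.780; the
forest reaches 0.746 from the 22 features alone, and the five APT bins
land on their nominal <5%/25%/50%/75%/>95% positive rates. The top Gini
importances are the citation rate (CPY) and the mean Human score of the
citing network (meanH) — the two levers of the planted mechanism.

The same pipeline runs from the shell on JSON-lines articles, a TSV edge
list and a MeSH vocabulary file (NLM ASCII descriptor format or
two-column TSV):

```sh
aptcite simulate --n 10000 --seed 7 --out corpus/
aptcite profile --vocab corpus/vocabulary.tsv --articles corpus/articles.jsonl \
                --edges corpus/edges.tsv --out profiles.tsv
aptcite train --profiles profiles.tsv --seed 1 --model model.joblib
aptcite predict --profiles profiles.tsv --model model.joblib --out apt.tsv
```

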