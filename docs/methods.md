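# Methods

## Content classification

Classification is purely address-based. A MeSH descriptor's tree
addresses are dot-separated paths; descent is the segment-prefix
relation. The six category rules are:

| Category | Rule |
|---|---|
| Human | address equals the Humans leaf (`B01.050.150.900.649.801.400.112.400.400`) or lies under `M01` |
| Animal | under `B01`, excluding the Humans leaf |
| Mol/Cell | under `A11`, `B02`, `B03`, `B04`, `G02.111.570` or `G02.149` |
| Disease (D) | under `C`, excluding `C22` (animal diseases) |
| Therapeutic (E) | under `E`, excluding `E07` (equipment) |
| Chem/Drug (CD) | under `D` |

Classification has *descriptor-level set semantics*: a descriptor counts
at most once per category however many of its addresses match, and a
descriptor may fall in several categories (e.g. a cultured-tumour-cell
descriptor is both Mol/Cell and Disease). Qualifier strings
(`Descriptor/qualifier`) and major-topic asterisks are stripped before
lookup. Unknown descriptors raise by default; a lenient mode logs and
skips them, which is the right behaviour for corpora indexed against a
newer vocabulary than the one supplied.

An article is *clinical* iff one of its publication types is a clinical
trial (any phase), a clinical study, or a guideline — matching on the
exact lowercase type strings. Citation by such an article is the
prediction target everywhere below.

## Fractional counting and the triangle

Fractional HAMC scores divide each of the Human/Animal/MolCell distinct-
descriptor counts by their three-way total. Articles with zero HAMC
terms get an explicit *undefined* score rather than an arbitrary corner;
they are excluded from triangle plots and curve groups. The trilinear
map is the barycentric interpolation of the vertex coordinates
(0, 1), (√3/2, −½), (−√3/2, −½); √3/2 is always computed, never the
decimal literal, and the simplex constraint is enforced to 1e-9. The
map is affine, so mixtures of scores map to mixtures of coordinates — a
property the tests exercise directly.

"Years post publication" is the integer calendar-year difference
(citation year − publication year) throughout; the data this pipeline
consumes is year-sliced, so no finer resolution is meaningful.

## Data profiles

The canonical 22-feature order is fixed and name-addressed:
`H A MC D E CD CPY` then
`maxH meanH sdH maxA meanA sdA maxMC meanMC sdMC meanD sdD meanE sdE meanCD sdCD`.
Conventions, all chosen to keep degenerate networks finite and the
feature count consistent:

* window `w` keeps citations with offset ≤ `w` (inclusive), with an
  `as_of_year` calendar variant; `restrict_network` is monotone in `w`;
* CPY = citations / (elapsed calendar years + 1), floored at one year;
  by default the rate uses the same window as the network summaries
  (`cpy_full_history` overrides);
* SDs are population SDs (÷ n), 0 for n ≤ 1;
* citers with undefined HAMC scores contribute zeros to the H/A/MC
  summaries but count in the flag means and in CPY;
* duplicate edges are distinct observations (the editing module's
  duplication control requires this).

`build_profiles` is the vectorised corpus-scale path (pandas groupby);
`build_profile` the single-article path. The tests assert the two agree
to machine precision on sampled articles.

## The classifier and the APT score

A scikit-learn random forest (default 100 trees — the reference
protocol does not fix a count; more trees sharpen the vote-fraction
resolution at linear cost) is trained after seeded downsampling of the
majority class to 2× the minority count, without replacement, never
touching minority rows. The raw prediction is the fraction of trees
voting positive — per-tree majority votes averaged, not averaged leaf
probabilities — so raw scores are multiples of 1/n_trees.

Vote fractions need not be linear in the true positive rate, so they are
calibrated into five contiguous bins targeting empirical positive rates
(0.05, 0.25, 0.50, 0.75, 0.95). The published description of this
binning is not an algorithm, so the package commits to one defensible
reading: candidate thresholds are midpoints between consecutive distinct
raw values (thinned to ≤400 near even quantiles), and a dynamic program
picks the four cuts minimising Σ(bin rate − target)² with all bins
non-empty. Consequences: thresholds are strictly increasing by
construction, bin membership is invariant under any rank-preserving
transform of the raw scores, and the calibration degrades gracefully
when the raw distribution cannot reach a target (the closest achievable
rate is reported in `bin_rates`). Calibration is fitted on a held-out
split, not the training split, to avoid optimistic bin rates.

Evaluation reports accuracy, F1, ROC/PR curves and AUC against the
test-set prevalence (chance rate); `repeated_holdout` mirrors the
repeated independent train/test protocol at configurable sizes.
Feature importances are normalised mean decreases in Gini impurity;
subgroup importances retrain on the subgroup (e.g. fundamental or
human-focused articles) rather than masking rows post hoc.
Article-only baselines are feature-subset masks (`hamc`, `hamc+flags`,
`article`), not separate code paths.

## Citation editing

Between two cumulative snapshots (year A ⊂ year B), the increment is
deleted and replaced by an equal number of synthetic citers: resampled
year-A citers (ORIGINALS, with replacement, seeded), or homogeneous
vertex citers (MOLCELL / ANIMAL / HUMAN), or HUMAN_PLUS (h = 1 and
D = E = CD = 1 — the strongest clinical-looking citer admissible, which
provably maximises meanH, meanD, meanE and meanCD simultaneously).
Network size is conserved exactly, so ΔAPT isolates citer content;
ORIGINALS isolates the citation-rate increase alone. A `replace_all`
flag swaps the whole network instead of the increment. ΔAPT is reported
both as the raw vote-fraction difference (high resolution) and as the
bin-value difference (comparable across experiments). Articles whose
year-A network is empty are dropped: ORIGINALS is undefined for them.
Synthetic citers implicitly carry the increment year, so they affect
CPY exactly as the deleted citations did.

## The synthetic corpus

The generator emulates the statistical structure the pipeline assumes,
with one top-level seed split into named substreams (content, network,
outcome), and is byte-reproducible.

**Content.** Articles draw an intended H/A/MC composition from a
four-component Dirichlet mixture — molecular/cellular fundamental
(weight 0.30, α = (0.4, 0.8, 6.0)), animal-model (0.25, (1.5, 5.0, 1.0)),
translational mixed (0.20, (3.0, 3.0, 1.5)), human clinical
(0.25, (6.0, 1.0, 0.4))) — then realise it as 1 + Poisson(3) distinct
descriptors drawn from the packaged ~54-descriptor vocabulary, so the
whole classification stack runs on real descriptor lists and the
recorded ground truth provably equals what scoring recomputes (tested).
Modifier flags are Bernoulli with probabilities affine in the
composition: `P(D) = 0.20 + 0.45·h + 0.35·a`, `P(E) = 0.15 + 0.55·h`,
`P(CD) = 0.35 + 0.20·h`. The Disease flag loads on animal content
deliberately: an in-vivo disease model is indexed under the disease it
models, and this is what places animal work between bench and bedside
rather than beside it. Articles are clinical with probability
0.02 + 0.25·h.

**Citation dynamics.** The network grows year by year. Each new article
draws Poisson(6) references; each reference proposes a target from the
preferential-attachment distribution ∝ (1 + in-degree)^0.8 and accepts
with probability exp(−d / 0.7), d the Euclidean triangle distance
between citing and cited compositions (rejected proposals are redrawn).
Citations carry the citing article's publication year; (citing, cited)
pairs are unique; edges are emitted year-sorted so cumulative snapshots
are prefixes.

**Outcome.** Each article's clinical-citation probability is
σ(β₀ + β_meanH·meanH + β_meanA·meanA + β_cpy·log1p(CPY) + β_meanD·meanD)
over its realised full-history network, with defaults
β₀ = −2.75, β_meanH = 2.2, β_meanA = 0.9, β_cpy = 1.0, β_meanD = 0.8;
the label is one Bernoulli draw. The animal coefficient is a modelling
necessity as much as a choice: per-citer scores satisfy H + A + MC = 1,
so without it the label would be independent of animal content given
(meanH, CPY, meanD), meanA and meanMC would be exchangeable complements,
and no citing-network experiment could order Animal against Mol/Cell
edits — the ordering would be an artefact of whichever surrogate splits
the forest happened to grow. Placing it between the Disease and Human
weights encodes that animal evidence is more translational than
molecular evidence and less than human evidence. The intercept centres
the default prevalence near 0.21, inside the 0.2–0.3 band typical of
mature literature corpora. Because the generative probability is
recorded per article, the Bayes AUC (probability-vs-label AUC) is an
exact ceiling for any classifier; the default corpus sits near 0.78 and
the forest reaches within 0.05 of it at n = 50,000.

**What is not emulated.** Field and journal structure, author effects,
indexing lag and vocabulary drift, secondary citation of reviews,
reference-list length correlations, and any real-data missingness.
Passing tests therefore certify the pipeline's correctness and the
recoverability of a planted mechanism — not performance levels on real
literature, which depend on how much signal real citing networks carry.

## Visualisation

Density maps accumulate unit (or weighted) point sources by
nearest-pixel binning on a 512×512 raster (configurable) over the
triangle's bounding box; accumulation conserves total weight exactly.
Smoothing is a separable Gaussian (σ in pixels, σ = 0 the identity),
which conserves mass away from raster-border clipping. Ratio maps
divide two smoothed grids with zero-denominator masking. The
pseudocolour palette is any matplotlib perceptually uniform map
(default viridis) with the value range exported as a legend; the raster
itself is exportable as TSV for regression testing.

## Problem sizes in the test suite

Module tests run on a 1,500-article corpus; the planted-mechanism,
editing and trajectory checks share one 50,000-article corpus
(≈290k edges) with a 25k/10k/15k train/calibration/test split; the
calibration property uses 100,000 synthetic probability draws. These
sizes give the property assertions comfortable statistical margins
while keeping the full suite under a minute of forest training.

## Known limitations

* The bin-calibration objective is one reading of an under-specified
  procedure; alternatives (e.g. isotonic regression followed by fixed
  cutpoints) would give slightly different thresholds with the same
  monotone semantics.
* `classify_address` implements one fixed vocabulary snapshot's branch
  layout; descriptors whose addresses moved across MeSH releases (the
  chemical-processes branch, notably) must be resolved by supplying the
  matching vocabulary file, not by the classifier.
* The forest's vote-fraction granularity is 1/n_trees; with the default
  100 trees, APT thresholds closer than 0.01 are not meaningful.
* Editing experiments condition on articles with non-empty year-A
  networks; conclusions do not extend to never-cited articles.
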