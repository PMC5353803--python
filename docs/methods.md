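# Methods

## The classification model

Each genus *g* is a multinomial distribution over the 4^K possible DNA
words of length K. Training counts every overlapping K-mer of every
training sequence into a per-genus row of a count matrix **X** (M genera
× 4^K words) and converts counts to log2-probabilities with additive
pseudo-counts:

    Q[g, j] = log2( (x_gj + P / 4^K) / (Σ_j x_gj + P) )

where the pseudo-count total P (default 100) is spread uniformly over
the 4^K words so that unseen words keep a small positive probability.
Rows of **Q** are exact probability distributions (Σ_j 2^Q[g,j] = 1).

A query is scored against all genera by summing, for each of its valid
K-mer windows, the corresponding *column* of **Q**. This streaming
formulation never materialises the query's 4^K-long count vector: a
query of length n costs at most (n − K + 1)·M column additions instead
of 4^K·M multiply–adds, which is cheaper whenever 4^K > n − K — for
full-length 16S (n ≈ 1500) the crossover is at K ≈ 5.27, so streaming
wins at every practical word length. The production configuration uses
K = 8 and P = 100; the score is a pure log-likelihood (flat prior over
genera), and the predicted genus is the arg-max row, ties broken to the
lowest training index.

Sequences are encoded A, C, G, T (or U) → 0..3; any other symbol (N and all
IUPAC ambiguity codes) becomes the sentinel −4^15, so any window
containing one has a negative inner product with [4^(K−1), …, 4, 1] and
is discarded. This is exact for K ≤ 15; the package caps K at 12 for
memory reasons. Fractional counting of ambiguity codes is deliberately
not done. Reads are scored as given (16S pipelines orient reads
upstream); an optional flag scores both strands and keeps the better
one.

## Uncertainty: d-scores

Raw maximum log-probabilities p₁ fall roughly linearly with sequence
length and their spread grows with length, so raw scores from reads of
different lengths are not comparable. At training time, one random
fragment per training sequence is sampled (length uniform on
[100, full length], start uniform), classified, and two linear
regressions are fitted: the mean of p₁ versus length, and the standard
deviation of the mean-line residuals versus length (residual SDs are
computed in length bins — 50-base bins when the training set populates
them, automatically widened otherwise — and a line is fitted through
the bin SDs). A score p at length l is then normalized to

    p~ = (p − p̂_l) / ŝ_l.

The d-score of a read is d = p̃₁ − p̃₂, the gap between its two best
normalized scores. d ≈ 0 means the read sits on a decision boundary
between two genera; d > 1 is in practice a safe classification. Because
both scores are normalized with the same affine map, d is invariant to
adding any constant to the raw scores and is non-negative by
construction.

## Uncertainty: r-scores and the novelty probability

Within each genus, the normalized training scores have a mean p̄_g and a
sample SD s_g. The r-score of a read classified to genus g is the
standardized residual

    r = (p̃₁ − p̄_g) / s̄_g ,

using the *predicted* genus as a plug-in. Many genera are small (down
to a single sequence), making s_g noisy or undefined, so the scale is
shrunk toward a size-specific estimate: raw SDs are grouped by genus
size n, the mean SD per size is smoothed against size with loess
(tricube-weighted local quadratic regression, span 0.75, implemented
in-package; predictions floored at the smallest positive fitted value,
sizes outside the fitted range mapped to the nearest fitted size), and

    s̄_g = sqrt( ((n − 1)·s_g² + s_n²) / n ) ,

which equals s_n exactly for singletons and converges to s_g as n grows.

Training r-scores (each sequence against its own genus) are stored
sorted; the novelty probability of a new read's r is the empirical CDF
value Pr(r_train ≤ r) with the Weibull plotting position rank/(N + 1),
so probabilities are never exactly 0 or 1; values below the training
minimum return 1/(N + 1) and are flagged "unusual". In the original
setting the ECDF comes from a larger companion collection than the
classifier's training set; here both are fitted on the same set.

## The word-presence baseline

For comparison the package carries a bootstrap-free RDP-style naive
Bayes classifier over distinct 8-mers: word prior
p_j = (n_j + 0.5)/(N + 1) and genus conditional
(m_gj + p_j)/(M_g + 1), scored by summing log conditionals over the
distinct words of the query. Duplicate words count once (presence, not
multiplicity). The bootstrap confidence machinery of the original tool
is intentionally omitted.

## The synthetic community generator

No public training collection ships with the package; all evaluations
run on synthetic communities designed to reproduce the structural
features of curated full-length 16S collections:

* **Nested similarity.** A random ancestor; order-like group centroids
  diverging from it; genus centroids diverging from their group; i.i.d.
  per-sequence substitutions (rate 0.015) around each genus centroid.
* **Conserved/variable architecture.** Between-taxon divergence is
  confined to nine evenly spaced variable blocks covering 35% of the
  1500-base gene, mimicking the V1–V9 regions. Short reads that land in
  conserved stretches carry little taxonomic signal — this, not overall
  distance, is what makes short reads misclassify more often.
* **Borderline genera.** Each group ends in a crowded clade of four
  genera only 0.6% of variable sites from a shared clade centroid, and
  in two groups the last clade member is a *sequence-level twin* of its
  neighbour: its training sequences are near-copies (0.5% per base) of
  the other genus's, emulating near-identical 16S deposited under
  different genus names (the Escherichia/Shigella situation). Twins are
  what keeps the long-read error rate non-zero: once a model is trained
  with pseudo-counts, any k-mer unique to a query's own training
  sequence is worth ~9 bits, so only shared training sequences can
  confuse long reads.
* **Unbalanced genus sizes.** Lognormal sizes (median ≈ 12, capped at
  60, singletons retained), echoing the ~20 sequences/genus balance and
  singleton tail of real collections.

Remaining defaults: 50 genera in 5 groups; group divergence 0.25 and
exponential per-genus branch lengths with mean 0.05, both over variable
sites. The `SyntheticCommunitySpec` class itself defaults to the plain
flat model (divergence everywhere, fixed branch lengths);
`default_community()` returns the structured study conditions above.

Read corruption uses exact-count semantics — round(rate·n) distinct
positions substituted with a base different from the original — so
small-fixture effects are deterministic (per-base Bernoulli mode is
available behind a flag). Indel corruption draws round(rate·n) anchor
positions and, per anchor, inserts or deletes (50/50) a fixed-length
block, applied right-to-left so anchors refer to the original
coordinates.

What the generator does **not** emulate: phylogenetically realistic
substitution processes (no rate heterogeneity beyond the
conserved/variable dichotomy, no transition/transversion bias), indel
evolution, chimeras, and the true continuum of inter-genus distances
(approximated by discrete tiers). Passing evaluations therefore
demonstrate that the machinery behaves as designed under realistic
*structure*, not that the specific error percentages transfer to any
particular real reference set.

## Evaluation experiments

* **Read-length experiment.** 10 fragments per training sequence at
  120–150, 270–300 and 450–500 bases; error rate, ROC AUC of the
  d-score as a correctness ranker, and error rate among d > 1.
* **Unknown-taxon experiment.** Each fragment is classified three ways
  from a single score matrix: against all genera; with its own genus's
  column excluded; with all columns of its group excluded. Excluding
  columns is mathematically identical to retraining without those taxa
  because rows of the per-taxon multinomial are independent; genus
  statistics of the remaining genera are unchanged by construction.
* **Corruption experiment.** A shared 450–500-base fragment set is
  corrupted per condition (1% and 5% substitutions; length-5 and
  length-10 indel blocks at 1% of positions) and reclassified.

With the default community (~750 sequences) the whole battery — build,
three experiments, determinism check — runs in well under a minute on
one core; these problem sizes were chosen as the package's scaled-down
study conditions.

## Numerical and design choices

* Log base 2 throughout; only score differences and ratios matter, but
  the base is recorded in the model archive.
* The pseudo-count enters *additively*; a subtractive variant is
  algebraically invalid for sparse rows (negative probabilities).
* Arg-max ties break to the lowest taxon index, deterministically; exact
  ties are flagged and give d = 0.
* Unscorable queries (shorter than K, or all windows containing
  ambiguous symbols) yield flagged NA records rather than being
  dropped, so output rows always match input rows; a single-taxon model
  yields d = NA.
* Lengths outside the normalization fit range are extrapolated and
  flagged; a non-positive predicted SD raises an error. The recorded
  fit range extends to the full training length even when no sampled
  fragment reached it.
* The length-normalization fit refuses to run with fewer than 100
  fragments (the SD regression is unstable below that) or with a
  degenerate length distribution (fewer than two populated bins).
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical
  serialized models and result tables. The model archive is a zip of
  `.npy` members plus a JSON manifest written with fixed timestamps so
  that equality can be checked at the byte level.

## Known limitations

* One model per taxonomic rank; no hierarchical roll-up, no bootstrap
  confidence, no chimera detection (corruption operators cover error
  robustness only qualitatively).
* The r-score ECDF is fitted on the same set as the classifier; with a
  small community its tail resolution is limited (N ≈ 750 gives a floor
  of ~1.3 × 10⁻³).
* loess smoothing of SD versus genus size needs at least one genus of
  size ≥ 2; a community of pure singletons cannot be fitted.
* The streaming classifier is pure NumPy; it processes a few thousand
  reads per second per core, which is ample for the package's scale but
  far from an optimized C++ implementation.
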