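"""How the d- and r-scores react to boundary cases and corrupted reads.

Classifies three kinds of 450-500-base reads with the same trained model:
clean reads, reads with 5% substitution errors, and reads from a genus
that was masked out of the score matrix (an "unknown" genus).  Clean
reads score d >> 1 and r near 0; corrupted reads keep their genus but
slide left in r (they look unusual); reads from an unknown genus get
strongly negative r-scores and tiny ECDF probabilities.
"""

import numpy as np

import microtax as mt

records, taxonomy = mt.generate_community(mt.default_community(seed=42))
model = mt.build_taxmachine(records, taxonomy, seed=42)
rng = np.random.default_rng(1)

reads = [
    (rid, mt.sample_fragment(seq, 450, 500, rng)) for rid, seq in records[:60]
]


def summarize(name, recs):
    d = np.array([r.d_score for r in recs if r.d_score is not None])
    rr = np.array([r.r_score for r in recs if r.r_score is not None])
    pp = np.array([r.r_probability for r in recs if r.r_probability is not None])
    print(
        f"{name:<22} median d = {np.median(d):7.2f}   "
        f"median r = {np.median(rr):8.2f}   median Pr(r) = {np.median(pp):.3g}"
    )


summarize("clean reads", mt.classify_with_uncertainty(reads, model))

corrupted = [(rid, mt.corrupt_substitutions(s, 0.05, rng)) for rid, s in reads]
summarize("5% substitutions", mt.classify_with_uncertainty(corrupted, model))

# emulate an unknown genus: classify its reads with its own column masked
unknown = mt.evaluate_unknown_taxa(
    model, records[:200], taxonomy, fragments_per_seq=2, seed=1
)
print(
    f"{'unknown-genus reads':<22} mean r = {unknown['genus_holdout']['mean_r']:8.2f}"
    f"   (in-training baseline {unknown['baseline']['mean_r']:+.2f})"
)
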