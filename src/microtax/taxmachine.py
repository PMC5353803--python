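"""Ready-to-use genus classifier with uncertainty scores, plus evaluations.

``build_taxmachine`` trains the full stack on a labelled FASTA set with
the production defaults (K=8 words, pseudo-count total 100): the
multinomial Q matrix, the length-normalization regressions fitted on one
random fragment per training sequence, and the per-genus score statistics
with the training r-score ECDF.  ``classify_with_uncertainty`` then emits
one record per query — predicted genus, d-score, r-score and its ECDF
probability — flagging unscorable queries, exact ties, lengths outside
the fitted range and unusually low r-scores, and never aborting a batch.

The evaluation helpers mirror the standard read-length, unknown-taxon and
read-corruption experiments on any labelled sequence set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import io as mio
from .multinomial import (
    LogProbMatrix,
    aggregate_taxon_counts,
    classify_streaming,
    predict_taxa,
    train_multinomial,
)
from .seqcodec import encode_sequence
from .synthetic import corrupt_indels, corrupt_substitutions, sample_fragment
from .uncertainty import (
    GenusScoreStats,
    LengthNormModel,
    fit_genus_stats,
    fit_length_norm_pairs,
    fragment_scores,
    normalize_logprob,
    r_probability,
)

DEFAULT_K = 8
DEFAULT_PSEUDO = 100.0

__all__ = [
    "TaxMachineModel",
    "ClassificationRecord",
    "build_taxmachine",
    "classify_with_uncertainty",
    "evaluate_fragments",
    "evaluate_unknown_taxa",
    "evaluate_corruption",
]


@dataclass
class TaxMachineModel:
    """Trained classifier bundle: Q matrix + length norm + genus statistics."""

    logprob: LogProbMatrix
    norm: LengthNormModel
    stats: GenusScoreStats
    metadata: dict

    @property
    def taxa(self) -> list[str]:
        return self.logprob.taxa


@dataclass
class ClassificationRecord:
    """One classified query with its uncertainty scores and flags."""

    query_id: str
    taxon: str | None
    d_score: float | None
    r_score: float | None
    r_probability: float | None
    flags: list[str] = field(default_factory=list)


def build_taxmachine(
    records: list[tuple[str, str]],
    taxonomy: pd.DataFrame,
    k: int = DEFAULT_K,
    pseudo_count: float = DEFAULT_PSEUDO,
    seed: int = 0,
    name: str = "custom",
) -> TaxMachineModel:
    """Train the full classification stack on labelled sequences.

    Every record must have a genus label in `taxonomy`.  The length
    normalization is fitted on one random fragment per training sequence
    (length uniform on [100, full length]); the same normalized fragment
    scores, grouped by true genus, feed the genus statistics and the
    training r-score ECDF.
    """
    labels_map = mio.taxonomy_map(records, taxonomy)
    labels = [labels_map[rid] for rid, _ in records]
    encoded = [encode_sequence(seq) for _, seq in records]
    counts = aggregate_taxon_counts(encoded, labels, k)
    logprob = train_multinomial(counts, pseudo_count)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    lengths, p1 = fragment_scores(logprob, encoded, rng)
    norm = fit_length_norm_pairs(lengths, p1)
    # full-length training sequences belong to the fitted population even
    # when no sampled fragment reached the maximum length
    full_max = max(len(e) for e in encoded)
    if full_max > norm.fit_range[1]:
        norm = replace(norm, fit_range=(norm.fit_range[0], int(full_max)))
    p_tilde = normalize_logprob(p1, lengths, norm, warn_extrapolate=False)
    stats = fit_genus_stats(p_tilde, labels)
    metadata = {
        "training_set": name,
        "n_sequences": len(records),
        "n_genera": len(logprob.taxa),
        "k": k,
        "pseudo_count": pseudo_count,
        "seed": int(seed),
        "format_version": mio.FORMAT_VERSION,
    }
    return TaxMachineModel(logprob=logprob, norm=norm, stats=stats, metadata=metadata)


def classify_with_uncertainty(
    queries: list[tuple[str, str]],
    model: TaxMachineModel,
    both_strands: bool = False,
) -> list[ClassificationRecord]:
    """Classify queries and attach d-score, r-score and ECDF probability.

    One output record per input record, in input order.  Flags:
    ``unscorable`` (no valid K-mer window), ``tie`` (exact top-two tie),
    ``extrapolated-length`` (outside the normalization fit range) and
    ``unusual`` (r-score below every training r-score).
    """
    encoded = [encode_sequence(seq) for _, seq in queries]
    scores = classify_streaming(encoded, model.logprob, both_strands=both_strands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = predict_taxa(scores, model.taxa)
    lo, hi = model.norm.fit_range
    out: list[ClassificationRecord] = []
    for i, (qid, _) in enumerate(queries):
        if not top.scorable[i]:
            out.append(
                ClassificationRecord(qid, None, None, None, None, ["unscorable"])
            )
            continue
        flags: list[str] = []
        length = int(scores.lengths[i])
        if length < lo or length > hi:
            flags.append("extrapolated-length")
        genus = model.taxa[top.best_index[i]]
        p1t = float(
            normalize_logprob(top.p1[i], length, model.norm, warn_extrapolate=False)
        )
        if np.isfinite(top.p2[i]):
            p2t = float(
                normalize_logprob(top.p2[i], length, model.norm, warn_extrapolate=False)
            )
            d = p1t - p2t
            if top.tie[i]:
                flags.append("tie")
        else:
            d = None  # single-taxon model: runner-up undefined
            flags.append("no-runner-up")
        gi = model.stats.genus_index(genus)
        r = (p1t - model.stats.mean[gi]) / model.stats.shrunk_sd[gi]
        prob = float(r_probability(r, model.stats))
        if r < model.stats.ecdf[0]:
            flags.append("unusual")
        out.append(ClassificationRecord(qid, genus, d, float(r), prob, flags))
    return out


# ---------------------------------------------------------------------------
# evaluation experiments


def _fragment_set(
    records: list[tuple[str, str]],
    labels: list[str],
    length_range: tuple[int, int],
    fragments_per_seq: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Random fragments (encoded), their true genus, and raw strings."""
    frags, truth, raw = [], [], []
    lo, hi = length_range
    for (rid, seq), lab in zip(records, labels):
        if len(seq) < lo:
            continue
        for _ in range(fragments_per_seq):
            frag = sample_fragment(seq, lo, hi, rng)
            frags.append(encode_sequence(frag))
            truth.append(lab)
            raw.append(frag)
    return frags, truth, raw


def _top_scores(model: TaxMachineModel, frags: list[np.ndarray]):
    scores = classify_streaming(frags, model.logprob)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = predict_taxa(scores, model.taxa)
    return scores, top


def evaluate_fragments(
    model: TaxMachineModel,
    records: list[tuple[str, str]],
    taxonomy: pd.DataFrame,
    length_ranges: tuple = ((120, 150), (270, 300), (450, 500)),
    fragments_per_seq: int = 10,
    seed: int = 0,
) -> dict:
    """Read-length experiment: error rate, d-score AUC, error among d > 1.

    For each length range, `fragments_per_seq` fragments are sampled per
    sequence at random locations and classified; the d-score is assessed
    as a ranker of correct vs incorrect classifications (ROC AUC), and the
    error rate is recomputed among the d > 1 subset (the "safe" zone).
    """
    labels_map = mio.taxonomy_map(records, taxonomy)
    labels = [labels_map[rid] for rid, _ in records]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    results: dict = {}
    for rangespec in length_ranges:
        frags, truth, _ = _fragment_set(records, labels, rangespec, fragments_per_seq, rng)
        scores, top = _top_scores(model, frags)
        ok = top.scorable
        pred = np.array([model.taxa[i] if i >= 0 else "" for i in top.best_index])
        correct = (pred == np.asarray(truth)) & ok
        lengths = scores.lengths.astype(float)
        p1t = normalize_logprob(top.p1, lengths, model.norm, warn_extrapolate=False)
        p2t = normalize_logprob(top.p2, lengths, model.norm, warn_extrapolate=False)
        d = p1t - p2t
        n = int(ok.sum())
        err = 1.0 - correct[ok].mean()
        if correct[ok].all() or not correct[ok].any():
            auc = float("nan")
        else:
            auc = float(roc_auc_score(correct[ok].astype(int), d[ok]))
        safe = ok & (d > 1.0)
        err_safe = float(1.0 - correct[safe].mean()) if safe.any() else float("nan")
        results[rangespec] = {
            "n_fragments": n,
            "error_rate": float(err),
            "d_auc": auc,
            "error_rate_d_above_1": err_safe,
        }
    return results


def _holdout_r(
    model: TaxMachineModel,
    scores,
    top_allowed_mask: np.ndarray,
) -> np.ndarray:
    """r-scores when argmax is restricted to an allowed-taxon mask per row."""
    rows = scores.scores.copy()
    rows[~top_allowed_mask] = -np.inf
    best = rows.argmax(axis=1)
    p1 = rows[np.arange(rows.shape[0]), best]
    lengths = scores.lengths.astype(float)
    p1t = normalize_logprob(p1, lengths, model.norm, warn_extrapolate=False)
    mean = np.array([model.stats.mean[model.stats.genus_index(model.taxa[b])] for b in best])
    sd = np.array(
        [model.stats.shrunk_sd[model.stats.genus_index(model.taxa[b])] for b in best]
    )
    return (p1t - mean) / sd


def evaluate_unknown_taxa(
    model: TaxMachineModel,
    records: list[tuple[str, str]],
    taxonomy: pd.DataFrame,
    fragment_range: tuple[int, int] = (450, 500),
    fragments_per_seq: int = 10,
    seed: int = 0,
    group_column: str = "group",
) -> dict:
    """Taxon-wise holdout: r-score distributions for novel genera/groups.

    Each fragment is classified three ways from one score matrix: against
    all taxa (baseline), excluding its own genus (genus holdout), and
    excluding every genus of its higher-rank group (group holdout, when a
    group column exists).  Excluding score-matrix columns is exactly
    equivalent to retraining without those taxa, because rows of the
    per-taxon multinomial are independent.
    """
    labels_map = mio.taxonomy_map(records, taxonomy)
    labels = [labels_map[rid] for rid, _ in records]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    frags, truth, _ = _fragment_set(records, labels, fragment_range, fragments_per_seq, rng)
    scores, top = _top_scores(model, frags)
    ok = top.scorable
    m = len(model.taxa)
    tax_index = {t: i for i, t in enumerate(model.taxa)}
    truth_idx = np.array([tax_index[t] for t in truth])
    nrow = len(frags)

    def summarize(r: np.ndarray) -> dict:
        r = r[ok]
        return {
            "mean_r": float(r.mean()),
            "median_r": float(np.median(r)),
            "n": int(r.size),
        }

    all_mask = np.ones((nrow, m), dtype=bool)
    baseline = summarize(_holdout_r(model, scores, all_mask))

    genus_mask = all_mask.copy()
    genus_mask[np.arange(nrow), truth_idx] = False
    if m < 2:
        raise ValueError("genus holdout needs at least two taxa")
    genus = summarize(_holdout_r(model, scores, genus_mask))

    out = {"baseline": baseline, "genus_holdout": genus}
    if group_column in taxonomy.columns:
        genus_group = dict(zip(taxonomy["genus"], taxonomy[group_column]))
        groups = np.array([genus_group[t] for t in model.taxa])
        frag_group = np.array([genus_group[t] for t in truth])
        group_mask = groups[None, :] != frag_group[:, None]
        if (group_mask.sum(axis=1) < 2).any():
            warnings.warn("a group holdout leaves fewer than two taxa; skipped",
                          stacklevel=2)
        else:
            out["group_holdout"] = summarize(_holdout_r(model, scores, group_mask))
    return out


def evaluate_corruption(
    model: TaxMachineModel,
    records: list[tuple[str, str]],
    taxonomy: pd.DataFrame,
    substitution_rates: tuple[float, ...] = (0.01, 0.05),
    indel_specs: tuple[tuple[float, int], ...] = ((0.01, 5), (0.01, 10)),
    fragment_range: tuple[int, int] = (450, 500),
    fragments_per_seq: int = 10,
    seed: int = 0,
) -> dict:
    """Sequencing-error experiment: accuracy and r-score quantiles.

    One shared fragment set is corrupted per condition (substitutions at
    the given rates; insertion/deletion blocks at the given position
    rates and lengths) and reclassified.
    """
    labels_map = mio.taxonomy_map(records, taxonomy)
    labels = [labels_map[rid] for rid, _ in records]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    _, truth, raw = _fragment_set(records, labels, fragment_range, fragments_per_seq, rng)

    def run(frag_strings: list[str]) -> dict:
        frags = [encode_sequence(s) for s in frag_strings]
        scores, top = _top_scores(model, frags)
        ok = top.scorable
        pred = np.array([model.taxa[i] if i >= 0 else "" for i in top.best_index])
        correct = (pred == np.asarray(truth)) & ok
        lengths = scores.lengths.astype(float)
        p1t = normalize_logprob(top.p1, lengths, model.norm, warn_extrapolate=False)
        mean = np.array(
            [model.stats.mean[model.stats.genus_index(p)] if p else np.nan for p in pred]
        )
        sd = np.array(
            [model.stats.shrunk_sd[model.stats.genus_index(p)] if p else np.nan for p in pred]
        )
        r = (p1t - mean) / sd
        q = np.percentile(r[ok], [25, 50, 75])
        return {
            "accuracy": float(correct[ok].mean()),
            "r_quantiles": {"q25": float(q[0]), "q50": float(q[1]), "q75": float(q[2])},
            "n": int(ok.sum()),
        }

    out = {"baseline": run(raw)}
    for rate in substitution_rates:
        out[f"sub_{rate:g}"] = run([corrupt_substitutions(s, rate, rng) for s in raw])
    for rate, ln in indel_specs:
        out[f"indel_{rate:g}x{ln}"] = run([corrupt_indels(s, rate, ln, rng) for s in raw])
    return out
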