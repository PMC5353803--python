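"""Bootstrap-free RDP-style word-presence naive Bayes genus classifier.

The classic RDP approach scores a query by the presence (not multiplicity)
of its 8-mers.  With N training sequences of which n_j contain word j, the
word prior is

    p_j = (n_j + 0.5) / (N + 1)

and for genus g with M_g sequences of which m_gj contain word j the
conditional is

    P(word j | g) = (m_gj + p_j) / (M_g + 1)

A query is assigned to the genus maximizing the sum of log conditionals
over its *distinct* words.  The bootstrap confidence machinery of the
original classifier is deliberately omitted; this implementation exists
as a comparison baseline and shares the integer K-mer engine with the
multinomial classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcodec import kmer_indices

DEFAULT_K = 8

__all__ = ["WordPresenceModel", "train_rdp", "classify_rdp", "classify_rdp_batch"]


@dataclass
class WordPresenceModel:
    """Per-genus log word-presence probabilities and the shared word prior."""

    log_cond: np.ndarray  # M x 4^K
    prior: np.ndarray  # 4^K
    genera: list[str]
    k: int


def _distinct_words(enc: np.ndarray, k: int) -> np.ndarray:
    return np.unique(kmer_indices(np.asarray(enc), k))


def train_rdp(
    sequences: list[np.ndarray], labels: list[str], k: int = DEFAULT_K
) -> WordPresenceModel:
    """Fit the word-presence model from encoded sequences and genus labels."""
    if len(sequences) == 0:
        raise ValueError("no training sequences")
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels differ in length")
    genera: list[str] = []
    index: dict[str, int] = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(genera)
            genera.append(lab)
    n_words = 4**k
    n_total = len(sequences)
    n_j = np.zeros(n_words, dtype=np.int64)
    m = np.zeros((len(genera), n_words), dtype=np.int64)
    sizes = np.zeros(len(genera), dtype=np.int64)
    for enc, lab in zip(sequences, labels):
        words = _distinct_words(enc, k)
        g = index[lab]
        sizes[g] += 1
        if words.size:
            n_j[words] += 1
            m[g, words] += 1
    prior = (n_j + 0.5) / (n_total + 1.0)
    log_cond = np.log((m + prior[None, :]) / (sizes[:, None] + 1.0))
    return WordPresenceModel(log_cond=log_cond, prior=prior, genera=genera, k=k)


def classify_rdp(enc: np.ndarray, model: WordPresenceModel) -> tuple[str, float]:
    """Assign an encoded query to the genus with maximal presence score.

    Duplicate words contribute once.  Ties break to the lowest genus index.

    Raises
    ------
    ValueError
        If the query has no valid K-mer window (unscorable).
    """
    words = _distinct_words(enc, model.k)
    if words.size == 0:
        raise ValueError("unscorable query: no valid K-mer window")
    scores = model.log_cond[:, words].sum(axis=1)
    g = int(scores.argmax())
    return model.genera[g], float(scores[g])


def classify_rdp_batch(
    queries: list[np.ndarray], model: WordPresenceModel
) -> list[tuple[str | None, float]]:
    """Batch variant; unscorable queries yield (None, nan) instead of raising."""
    out: list[tuple[str | None, float]] = []
    for enc in queries:
        try:
            out.append(classify_rdp(enc, model))
        except ValueError:
            out.append((None, float("nan")))
    return out
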