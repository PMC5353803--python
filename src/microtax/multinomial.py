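"""Multinomial K-mer model: training and streaming classification.

Each taxon g is modelled as a multinomial over the 4^K possible K-mers.
Training aggregates K-mer counts per taxon into a matrix X (M x 4^K) and
converts them to log2-probabilities with additive pseudo-counts:

    Q[g, j] = log2( (x_gj + P/4^K) / (sum_j x_gj + P) )

where P is the total pseudo-count mass spread uniformly over the 4^K
words.  A query of length n is scored against all M taxa by summing, for
each of its (at most n-K+1) valid K-mers, the corresponding column of Q —
the 4^K-long count vector of the query is never materialised, so the work
per query is (n-K+1)*M column additions instead of 4^K*M multiply-adds.
For full-length 16S (n ~ 1500) the streaming route is cheaper whenever
4^K > n - K, i.e. for word lengths above ~5.27.

The classifier uses a flat prior over taxa: scores are pure log-likelihoods
and only their differences matter downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .seqcodec import kmer_indices, reverse_complement

__all__ = [
    "TaxonCountMatrix",
    "LogProbMatrix",
    "PosteriorScores",
    "TopTwo",
    "aggregate_taxon_counts",
    "train_multinomial",
    "classify_streaming",
    "predict_taxa",
    "breakeven_word_length",
]


@dataclass
class TaxonCountMatrix:
    """Per-taxon K-mer counts: M taxa x 4^K words."""

    X: np.ndarray
    taxa: list[str]
    k: int

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon names")
        if self.X.shape != (len(self.taxa), 4**self.k):
            raise ValueError("count matrix shape does not match taxa/K")


@dataclass
class LogProbMatrix:
    """Multinomial log2-probabilities with pseudo-counts (the Q matrix)."""

    Q: np.ndarray
    taxa: list[str]
    k: int
    pseudo_count: float
    log_base: int = 2

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class PosteriorScores:
    """Posterior log2-probabilities for N queries x M taxa.

    Rows for unscorable queries (shorter than K, or no valid K-mer window)
    are all-zero with ``scorable`` False.
    """

    scores: np.ndarray
    lengths: np.ndarray
    scorable: np.ndarray


@dataclass
class TopTwo:
    """Best and runner-up taxon per query, with their log-probabilities."""

    best_index: np.ndarray
    second_index: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    tie: np.ndarray
    scorable: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def best_taxon(self, i: int) -> str | None:
        if not self.scorable[i]:
            return None
        return self.taxa[self.best_index[i]]


def aggregate_taxon_counts(
    sequences: list[np.ndarray], labels: list[str], k: int
) -> TaxonCountMatrix:
    """Sum K-mer counts of encoded sequences per taxon.

    Taxa are ordered by first appearance in `labels`.  A taxon whose
    sequences contain no valid K-mer at all keeps a row of zeros (warned).
    """
    if len(sequences) == 0:
        raise ValueError("no training sequences")
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels differ in length")
    taxa: list[str] = []
    index: dict[str, int] = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(taxa)
            taxa.append(lab)
    X = np.zeros((len(taxa), 4**k), dtype=np.int64)
    for enc, lab in zip(sequences, labels):
        idx = kmer_indices(np.asarray(enc), k)
        if idx.size:
            np.add.at(X[index[lab]], idx, 1)
    empty = np.flatnonzero(X.sum(axis=1) == 0)
    for g in empty:
        warnings.warn(f"taxon {taxa[g]!r} has zero valid K-mers", stacklevel=2)
    return TaxonCountMatrix(X=X, taxa=taxa, k=k)


def train_multinomial(X: TaxonCountMatrix, pseudo_count: float) -> LogProbMatrix:
    """Convert taxon counts to the Q matrix of log2-probabilities.

    The pseudo-count total P is spread uniformly: each cell receives
    P/4^K, each row total grows by P.  All-zero rows become the uniform
    distribution.
    """
    if pseudo_count <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo_count}")
    n_words = 4**X.k
    counts = X.X.astype(np.float64)
    row_tot = counts.sum(axis=1, keepdims=True)
    Q = np.log2((counts + pseudo_count / n_words) / (row_tot + pseudo_count))
    return LogProbMatrix(Q=Q, taxa=list(X.taxa), k=X.k, pseudo_count=float(pseudo_count))


def _score_one(enc: np.ndarray, model: LogProbMatrix) -> np.ndarray | None:
    idx = kmer_indices(enc, model.k)
    if idx.size == 0:
        return None
    # streaming: gather + sum columns of Q; never builds the 4^K count vector
    return model.Q[:, idx].sum(axis=1)


def classify_streaming(
    queries: list[np.ndarray],
    model: LogProbMatrix,
    both_strands: bool = False,
) -> PosteriorScores:
    """Score each encoded query against every taxon by streaming summation.

    With ``both_strands`` the reverse complement is also scored and the
    strand with the larger maximum is kept.  Unscorable queries (no valid
    window) get a zero row and a False ``scorable`` flag; the batch never
    aborts.
    """
    if len(queries) == 0:
        raise ValueError("no queries")
    n, m = len(queries), model.n_taxa
    scores = np.zeros((n, m), dtype=np.float64)
    lengths = np.zeros(n, dtype=np.int64)
    scorable = np.zeros(n, dtype=bool)
    for i, enc in enumerate(queries):
        enc = np.asarray(enc)
        lengths[i] = enc.size
        row = _score_one(enc, model)
        if both_strands:
            row_rc = _score_one(reverse_complement(enc), model)
            if row is None or (row_rc is not None and row_rc.max() > row.max()):
                row = row_rc
        if row is None:
            continue
        scores[i] = row
        scorable[i] = True
    return PosteriorScores(scores=scores, lengths=lengths, scorable=scorable)


def predict_taxa(scores: PosteriorScores, taxa: list[str]) -> TopTwo:
    """Best and second-best taxon per query from a score matrix.

    Ties break to the lowest taxon index (training order).  With a single
    taxon, p2 is -inf and the second index -1.  Unscorable rows yield
    best index -1 and NaN log-probabilities.
    """
    n, m = scores.scores.shape
    best = np.full(n, -1, dtype=np.int64)
    second = np.full(n, -1, dtype=np.int64)
    p1 = np.full(n, np.nan)
    p2 = np.full(n, -np.inf)
    tie = np.zeros(n, dtype=bool)
    ok = scores.scorable
    if ok.any():
        rows = scores.scores[ok]
        b = rows.argmax(axis=1)  # argmax returns the first (lowest) index on ties
        best[ok] = b
        p1[ok] = rows[np.arange(rows.shape[0]), b]
        if m > 1:
            masked = rows.copy()
            masked[np.arange(rows.shape[0]), b] = -np.inf
            s = masked.argmax(axis=1)
            second[ok] = s
            p2[ok] = masked[np.arange(rows.shape[0]), s]
            tie[ok] = p1[ok] == p2[ok]
    if m == 1:
        warnings.warn("single-taxon model: runner-up probability undefined", stacklevel=2)
    return TopTwo(best_index=best, second_index=second, p1=p1, p2=p2, tie=tie,
                  scorable=ok.copy(), taxa=list(taxa))


def breakeven_word_length(n: float = 1500.0) -> float:
    """Word length K at which streaming stops being cheaper: 4^K = n - K.

    Per query the streaming route costs (n-K)*M column additions versus
    4^K*M for the explicit matrix product; for n=1500 the crossover is at
    K ~ 5.27, so streaming wins for all practical word lengths (K >= 6).
    """
    return float(brentq(lambda k: 4.0**k - (n - k), 0.1, 15.0, xtol=1e-12))
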