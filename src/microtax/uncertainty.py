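"""Classification-uncertainty machinery: length normalization, d- and r-scores.

Two distinct kinds of uncertainty are quantified:

* Decision-boundary uncertainty (the d-score).  Raw posterior
  log2-probabilities shrink roughly linearly with sequence length (more
  K-mers, more negative terms), and their spread grows with length.  Two
  linear regressions — mean and standard deviation of the maximum
  log-probability versus length — turn a raw score p into the normalized

      p~ = (p - p_hat(l)) / s_hat(l)

  and the d-score is the gap between the best and second-best normalized
  scores.  d near 0 means the query sits on a decision boundary; d > 1 is
  in practice a safe classification.

* Novelty (the r-score).  Within each genus the normalized maxima of the
  training sequences have a mean p_bar_g and standard deviation s_g.  The
  r-score of a query is the standardized residual against its *predicted*
  genus: r = (p~ - p_bar_g) / s_bar_g.  Because many genera are tiny (down
  to a single sequence), s_g is unreliable or undefined; it is shrunk
  toward a loess-smoothed size-specific estimate s_n:

      s_bar_g = sqrt( ((n-1) s_g^2 + s_n^2) / n )

  which equals s_n exactly for singleton genera and converges to s_g as n
  grows.  An empirical CDF of training r-scores converts any r into the
  probability of seeing one at least as small among training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .multinomial import LogProbMatrix, classify_streaming, predict_taxa

__all__ = [
    "LengthNormModel",
    "GenusScoreStats",
    "fit_length_norm",
    "fit_length_norm_pairs",
    "normalize_logprob",
    "d_score",
    "loess_smooth",
    "fit_genus_stats",
    "r_score",
    "r_probability",
]

MIN_FRAGMENT_LEN = 100
MIN_FIT_FRAGMENTS = 100


@dataclass
class LengthNormModel:
    """Linear models for mean and SD of the max posterior log2-probability
    as functions of sequence length, fitted on random training fragments."""

    mean_coef: tuple[float, float]  # (intercept, slope)
    sd_coef: tuple[float, float]
    fit_range: tuple[int, int]

    def predict_mean(self, length):
        a, b = self.mean_coef
        return a + b * np.asarray(length, dtype=float)

    def predict_sd(self, length):
        a, b = self.sd_coef
        return a + b * np.asarray(length, dtype=float)


def sample_training_fragments(
    sequences: list[np.ndarray],
    rng: np.random.Generator,
    min_len: int = MIN_FRAGMENT_LEN,
) -> list[np.ndarray]:
    """One random fragment per training sequence.

    Fragment length is uniform on [min_len, full length] (sequences shorter
    than min_len are used whole), start position uniform.
    """
    frags = []
    for enc in sequences:
        n = len(enc)
        if n <= min_len:
            frags.append(np.asarray(enc))
            continue
        length = int(rng.integers(min_len, n + 1))
        start = int(rng.integers(0, n - length + 1))
        frags.append(np.asarray(enc)[start : start + length])
    return frags


def fragment_scores(
    model: LogProbMatrix,
    sequences: list[np.ndarray],
    rng: np.random.Generator,
    min_len: int = MIN_FRAGMENT_LEN,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify one random fragment per training sequence.

    Returns (lengths, p1): fragment lengths and the maximum posterior
    log2-probability of each fragment under `model`.
    """
    frags = sample_training_fragments(sequences, rng, min_len=min_len)
    scores = classify_streaming(frags, model)
    top = predict_taxa(scores, model.taxa)
    if not top.scorable.all():
        bad = int((~top.scorable).sum())
        warnings.warn(f"{bad} training fragments were unscorable", stacklevel=2)
    ok = top.scorable
    return scores.lengths[ok].astype(float), top.p1[ok]


def fit_length_norm_pairs(
    lengths: np.ndarray,
    p1: np.ndarray,
    bin_width: int | None = None,
    min_bin_size: int = 10,
) -> LengthNormModel:
    """Fit the two length regressions from (length, p1) observations.

    The mean model is an ordinary least-squares line through all points.
    For the SD model, points are binned by length; each bin with at least
    ``min_bin_size`` members contributes the sample SD of the residuals
    from the mean line at the bin midpoint, and a line is fitted through
    those.  (Binning the raw scores instead would fold the steep mean
    trend across each bin into the SD estimate.)  The default bin width
    is 50 bases, widened automatically when there are too few fragments
    to populate 50-base bins.
    """
    lengths = np.asarray(lengths, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if lengths.size < MIN_FIT_FRAGMENTS:
        raise ValueError(
            f"need at least {MIN_FIT_FRAGMENTS} fragments to fit the length "
            f"normalization, got {lengths.size}"
        )
    slope, intercept = np.polyfit(lengths, p1, 1)
    resid = p1 - (intercept + slope * lengths)
    lmin, lmax = float(lengths.min()), float(lengths.max())
    if bin_width is None:
        span = max(lmax - lmin, 1.0)
        n_bins = max(2, min(int(span // 50), lengths.size // (2 * min_bin_size)))
        bin_width = int(np.ceil(span / n_bins))
    edges = np.arange(np.floor(lmin), lmax + bin_width, bin_width)
    which = np.digitize(lengths, edges) - 1
    mids, sds = [], []
    for b in range(len(edges)):
        sel = which == b
        if sel.sum() >= min_bin_size:
            mids.append(edges[b] + bin_width / 2.0)
            sds.append(resid[sel].std(ddof=1))
    if len(mids) < 2:
        raise ValueError(
            "degenerate length distribution: fewer than two populated length "
            "bins, cannot fit the SD regression"
        )
    sd_slope, sd_intercept = np.polyfit(mids, sds, 1)
    m = LengthNormModel(
        mean_coef=(float(intercept), float(slope)),
        sd_coef=(float(sd_intercept), float(sd_slope)),
        fit_range=(int(lmin), int(lmax)),
    )
    if m.predict_sd(lmin) <= 0 or m.predict_sd(lmax) <= 0:
        raise ValueError("fitted SD regression is non-positive inside the fit range")
    return m


def fit_length_norm(
    model: LogProbMatrix,
    sequences: list[np.ndarray],
    seed: int | np.random.Generator = 0,
    min_len: int = MIN_FRAGMENT_LEN,
) -> LengthNormModel:
    """Sample one fragment per training sequence, classify, fit both lines."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths, p1 = fragment_scores(model, sequences, rng, min_len=min_len)
    return fit_length_norm_pairs(lengths, p1)


def normalize_logprob(p, length, model: LengthNormModel, warn_extrapolate: bool = True):
    """Length-normalize posterior log2-probabilities: (p - p_hat)/s_hat.

    Vectorized over p/length.  Lengths outside the fitted range are
    extrapolated with a warning; a non-positive predicted SD is an error.
    """
    p = np.asarray(p, dtype=float)
    length = np.asarray(length, dtype=float)
    lo, hi = model.fit_range
    outside = (length < lo) | (length > hi)
    if warn_extrapolate and np.any(outside):
        warnings.warn(
            f"normalizing at lengths outside the fitted range [{lo}, {hi}]",
            stacklevel=2,
        )
    sd = model.predict_sd(length)
    if np.any(sd <= 0):
        raise ValueError("predicted SD is non-positive at the requested length")
    return (p - model.predict_mean(length)) / sd


def d_score(p1_tilde, p2_tilde):
    """Gap between the two largest normalized posterior log-probabilities."""
    return np.asarray(p1_tilde, dtype=float) - np.asarray(p2_tilde, dtype=float)


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Loess (tricube-weighted local polynomial) fit evaluated at the x's.

    Local regression of the given degree in a window covering a `span`
    fraction of the points nearest each target.  With too few points the
    degree is reduced; a single point is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("no points to smooth")
    if n == 1:
        return y.copy()
    r = max(degree + 1, int(np.ceil(span * n)))
    r = min(r, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        order = np.argsort(d, kind="stable")[:r]
        h = d[order].max()
        if h == 0:
            out[i] = y[order].mean()
            continue
        w = (1 - (d[order] / h) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        deg = min(degree, order.size - 1)
        coef = np.polyfit(x[order], y[order], deg, w=np.sqrt(w))
        out[i] = np.polyval(coef, x[i])
    return out


@dataclass
class GenusScoreStats:
    """Per-genus location/scale of normalized scores plus the training ECDF.

    Arrays are aligned with `genera`: size n, mean p_bar, raw SD s (NaN for
    singletons), size-smoothed SD s_n, shrunken SD s_bar.  `ecdf` is the
    sorted vector of training r-scores.
    """

    genera: list[str]
    sizes: np.ndarray
    mean: np.ndarray
    raw_sd: np.ndarray
    size_sd: np.ndarray
    shrunk_sd: np.ndarray
    ecdf: np.ndarray

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genera)}
        if np.any(self.shrunk_sd <= 0):
            raise ValueError("shrunken SD must be positive for every genus")
        if np.any(np.diff(self.ecdf) < 0):
            raise ValueError("ECDF vector must be sorted")

    def genus_index(self, genus: str) -> int:
        try:
            return self._index[genus]
        except KeyError:
            raise KeyError(f"genus {genus!r} not present in the fitted statistics")


def shrink_sd(raw_sd: float, size_sd: float, n: int) -> float:
    """Shrink a genus SD toward the size-specific estimate.

    s_bar = sqrt(((n-1) s^2 + s_n^2) / n); undefined raw SDs (n = 1) are
    treated as zero, so a singleton genus gets exactly s_n.
    """
    s2 = 0.0 if (n < 2 or not np.isfinite(raw_sd)) else float(raw_sd) ** 2
    return float(np.sqrt(((n - 1) * s2 + float(size_sd) ** 2) / n))


def fit_genus_stats(p_tilde: np.ndarray, labels: list[str]) -> GenusScoreStats:
    """Per-genus statistics of normalized max log-probabilities + training ECDF.

    Raw per-genus SDs are grouped by genus size, the mean SD per size is
    loess-smoothed against size (span 0.75, degree 2, floored at the
    smallest positive fitted value), and each genus SD is shrunk toward
    its size's smoothed value.  Training r-scores are computed with each
    sequence's own genus and stored sorted for the ECDF.
    """
    p_tilde = np.asarray(p_tilde, dtype=float)
    if p_tilde.size != len(labels):
        raise ValueError("scores and labels differ in length")
    genera = sorted(set(labels))
    lab_arr = np.asarray(labels)
    sizes = np.empty(len(genera), dtype=np.int64)
    mean = np.empty(len(genera))
    raw_sd = np.full(len(genera), np.nan)
    for i, g in enumerate(genera):
        vals = p_tilde[lab_arr == g]
        sizes[i] = vals.size
        mean[i] = vals.mean()
        if vals.size >= 2:
            raw_sd[i] = vals.std(ddof=1)
    has_sd = np.isfinite(raw_sd)
    if not has_sd.any():
        raise ValueError("every genus is a singleton: no SD can be estimated")
    # mean raw SD per distinct genus size, loess-smoothed over size
    sd_sizes = np.unique(sizes[has_sd])
    mean_sd_by_size = np.array(
        [raw_sd[has_sd & (sizes == s)].mean() for s in sd_sizes]
    )
    smoothed = loess_smooth(sd_sizes.astype(float), mean_sd_by_size)
    positive = smoothed[smoothed > 0]
    if positive.size == 0:
        raise ValueError("loess-smoothed SDs are all non-positive")
    smoothed = np.maximum(smoothed, positive.min())
    # map every genus size (including sizes with no SD, e.g. 1) to the
    # nearest size at which the smoother was fitted
    size_sd = np.empty(len(genera))
    fitted_for = set(sd_sizes.tolist())
    for i, n in enumerate(sizes):
        j = int(np.abs(sd_sizes - n).argmin())
        if int(n) not in fitted_for and int(n) > 1:
            warnings.warn(
                f"genus size {int(n)} outside the smoothed range; using nearest "
                f"fitted size {int(sd_sizes[j])}",
                stacklevel=2,
            )
        size_sd[i] = smoothed[j]
    shrunk = np.array(
        [shrink_sd(raw_sd[i], size_sd[i], int(sizes[i])) for i in range(len(genera))]
    )
    gidx = {g: i for i, g in enumerate(genera)}
    gi = np.array([gidx[l] for l in lab_arr])
    r_train = (p_tilde - mean[gi]) / shrunk[gi]
    return GenusScoreStats(
        genera=genera,
        sizes=sizes,
        mean=mean,
        raw_sd=raw_sd,
        size_sd=size_sd,
        shrunk_sd=shrunk,
        ecdf=np.sort(r_train),
    )


def r_score(p_tilde, genus: str, stats: GenusScoreStats):
    """Standardized residual of p~ against the (predicted) genus centre."""
    i = stats.genus_index(genus)
    return (np.asarray(p_tilde, dtype=float) - stats.mean[i]) / stats.shrunk_sd[i]


def r_probability(r, stats: GenusScoreStats):
    """ECDF probability Pr(r_train <= r) with the rank/(N+1) convention.

    Never returns 0: values below the training minimum map to 1/(N+1)
    (an "unusual" observation, not an impossible one).
    """
    n = stats.ecdf.size
    rank = np.searchsorted(stats.ecdf, np.asarray(r, dtype=float), side="right")
    return np.maximum(rank, 1) / (n + 1)
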