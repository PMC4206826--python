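"""Population-level statistics.

Pattern similarity across stimulus repetitions (cosine similarity of N-cell
response vectors, averaged over the three repetition pairs), occurrence
reliability (Cronbach's alpha with a Feldt 95% confidence interval),
responder distributions, two-sample Kolmogorov-Smirnov comparison, and the
per-animal correlation between dopaminergic calcium influx and sensory
response gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "SimilarityResult", "ReliabilityResult", "ResponderDistribution",
    "cosine_similarity", "pattern_similarity", "cronbach_alpha",
    "responder_distribution", "ks_two_sample", "correlate_response_gain",
]


@dataclass(frozen=True)
class SimilarityResult:
    """Pairwise cosines between the three repetitions and their mean."""

    pair_12: float
    pair_23: float
    pair_13: float

    @property
    def mean_cosine(self) -> float:
        return (self.pair_12 + self.pair_23 + self.pair_13) / 3.0


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    ci95: tuple[float, float]
    n_items: int
    n_subjects: int


@dataclass(frozen=True)
class ResponderDistribution:
    counts: np.ndarray
    bin_edges: np.ndarray
    fraction_above: float      # nan when the input is empty
    n: int

    @property
    def fraction_defined(self) -> bool:
        return self.n > 0


def cosine_similarity(u, v) -> float:
    """cos(angle) = dot(u, v) / (||u|| * ||v||).

    Zero-norm vectors raise: silently mapping them to a similarity of 0 would
    bias averaged similarities, so callers must drop degenerate repetitions
    explicitly.  Negative dF/F entries are legitimate; the cosine may be
    negative.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def pattern_similarity(v1, v2, v3) -> SimilarityResult:
    """Cosines between repetitions (1,2), (2,3), (1,3); the mean is the pattern
    similarity of the time point."""
    return SimilarityResult(
        pair_12=cosine_similarity(v1, v2),
        pair_23=cosine_similarity(v2, v3),
        pair_13=cosine_similarity(v1, v3),
    )


def cronbach_alpha(scores, confidence: float = 0.95) -> ReliabilityResult:
    """Cronbach's alpha for a repetitions x cells score matrix.

    Rows are the k items (stimulus repetitions), columns the subjects
    (cells); binary occurrence matrices (0/1) are accepted.  With item
    variances :math:`v_i` (over subjects, ddof=1) and total-score variance
    :math:`v_T`,

        alpha = k/(k-1) * (1 - sum_i v_i / v_T).

    The confidence interval is Feldt's F interval with ``n_subjects - 1`` and
    ``(n_subjects - 1)(k - 1)`` degrees of freedom.
    """
    mat = np.atleast_2d(np.asarray(scores, dtype=float))
    k, n = mat.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items (repetitions)")
    if n < 2:
        raise ValueError("Cronbach's alpha needs at least 2 subjects (cells)")
    item_var = mat.var(axis=1, ddof=1)
    total_var = mat.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    alpha = k / (k - 1.0) * (1.0 - item_var.sum() / total_var)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    q = (1.0 - confidence) / 2.0
    lower = 1.0 - (1.0 - alpha) * stats.f.isf(q, df1, df2)
    upper = 1.0 - (1.0 - alpha) * stats.f.ppf(q, df1, df2)
    return ReliabilityResult(
        alpha=float(alpha), ci95=(float(lower), float(upper)),
        n_items=k, n_subjects=n,
    )


def responder_distribution(values, threshold: float = 0.2, bin_edges=None) -> ResponderDistribution:
    """Histogram of per-cell responses and the fraction strictly above threshold.

    The 0.2 dF/F default marks the "high responder" criterion used for the
    population distribution summaries.
    """
    x = np.asarray(values, dtype=float)
    if x.size and not np.isfinite(x).all():
        raise ValueError("response values must be finite")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 0.65, 0.05)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing")
    counts, _ = np.histogram(x, bins=edges)
    frac = float((x > threshold).mean()) if x.size else float("nan")
    return ResponderDistribution(counts=counts, bin_edges=edges,
                                 fraction_above=frac, n=int(x.size))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of |ECDF_x - ECDF_y| over the pooled sample points; the
    p-value uses the asymptotic Kolmogorov distribution with effective size
    ``n*m/(n+m)`` (adequate at the ~50-80 cells per animal this package
    handles).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n
    cdf_y = np.searchsorted(y, pooled, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    en = np.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    return d, min(p, 1.0)


def correlate_response_gain(vta_response, response_gain) -> tuple[float, float]:
    """Pearson correlation between a cell's dopaminergic calcium influx and
    its sensory response gain, within one animal.

    ``vta_response`` — per-cell summed dF/F evoked by phasic VTA stimulation;
    ``response_gain`` — per-cell dF/F(2hr - before) change.  Returns (r, p)
    two-sided.
    """
    x = np.asarray(vta_response, dtype=float)
    y = np.asarray(response_gain, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need at least 3 paired cells")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
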