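"""Baseline normalization and single-cell transient quantification.

The fluorescence change of a cell is dF/F = (F1 - F0)/F0, where F1 is the
raw fluorescence at a frame and F0 is the *sliding median baseline*: the
median of raw values within +/- a half window around that frame.  Two window
dialects are used, matched to the transient kinetics being quantified:

* +/- 40 s for the slow, long-lasting dopaminergic (VTA-evoked) transients,
* +/- 2.5 s for the fast sensory (V2L-evoked) transients.

Windows truncate at the recording boundaries (no padding).  Time conventions
throughout: 0-based frames, frame k occurs at ``k / fps`` seconds, analysis
windows are half-open ``[start, end)`` on timestamps.

Transient decay is quantified by fitting ``dF/F(t) = dF/F_max * exp(-t/tau)``
with ``dF/F_max`` pinned to the observed peak and ``t`` the time elapsed
after the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit

__all__ = [
    "DffMatrix", "DecayFit", "SummedResponse",
    "compute_dff", "fit_decay", "summed_response", "changing_ratio",
    "peak_response", "detect_occurrence", "response_vector",
]

VTA_HALF_WINDOW_S = 40.0
V2L_HALF_WINDOW_S = 2.5


@dataclass
class DffMatrix:
    """Baseline-normalized fluorescence, cells x frames."""

    dff: np.ndarray
    fps: float
    baseline_half_window_s: float
    events: tuple = ()
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.dff.shape[0])

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.dff.shape[1]) / self.fps


@dataclass(frozen=True)
class DecayFit:
    dff_max: float
    tau_s: float
    fit_window: tuple[float, float]  # (start_s, end_s), absolute recording time
    rss: float
    n_samples: int


class SummedResponse(NamedTuple):
    summed_dff: float
    n_samples: int


def _window_half_width(half_window_s: float, fps: float) -> int:
    # frames j belong to the window of frame i iff |j - i| <= half_window_s * fps
    return int(np.floor(half_window_s * fps))


def compute_dff(trace, fps: float, half_window_s: float):
    """Sliding-median dF/F.

    ``F0[t]`` is the median of the raw samples whose frame index lies within
    ``half_window_s * fps`` frames of ``t`` (window truncated at the
    recording edges); ``dff[t] = (trace[t] - F0[t]) / F0[t]``.

    ``trace`` may be a 1-D trace or a cells x frames matrix (the window runs
    along the last axis).  Raises if any F0 is zero, naming the sample.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.size == 0:
        raise ValueError("trace must have at least one sample")
    if not (fps > 0):
        raise ValueError("fps must be positive")
    if not (half_window_s > 0):
        raise ValueError("half_window_s must be positive")
    squeeze = arr.ndim == 1
    mat = np.atleast_2d(arr)
    n = mat.shape[1]
    h = _window_half_width(half_window_s, fps)

    f0 = np.empty_like(mat)
    lo_edge = min(h, n - 1)
    hi_start = max(n - h, lo_edge)
    if n >= 2 * h + 1:
        windows = sliding_window_view(mat, 2 * h + 1, axis=1)
        f0[:, h : n - h] = np.median(windows, axis=-1)
    for i in range(min(h, n)):
        f0[:, i] = np.median(mat[:, : i + h + 1], axis=1)
    for i in range(hi_start, n):
        f0[:, i] = np.median(mat[:, max(0, i - h) :], axis=1)

    zero = np.argwhere(f0 == 0)
    if zero.size:
        c, s = zero[0]
        raise ValueError(f"baseline F0 is zero at cell {c}, sample {s}")
    dff = (mat - f0) / f0
    return dff[0] if squeeze else dff


def _default_fit_end(dff, peak_index, fps, floor_frac=0.05, max_fit_s=40.0):
    """Decay-fit extent: up to the first sample below 5% of the peak, capped at 40 s."""
    peak = dff[peak_index]
    cap = min(len(dff) - 1, peak_index + int(np.floor(max_fit_s * fps)))
    below = np.nonzero(dff[peak_index + 1 : cap + 1] < floor_frac * peak)[0]
    return peak_index + 1 + below[0] if below.size else cap


def fit_decay(
    dff, fps: float, peak_index: int, fit_end_index: int | None = None,
    method: str = "nls",
) -> DecayFit:
    """Fit the post-peak exponential decay and return its time constant.

    The model is ``dff(t) = dff_max * exp(-t / tau)`` with ``dff_max`` fixed
    to the observed value at ``peak_index`` and ``t`` measured from the peak.
    ``method="nls"`` fits tau by nonlinear least squares on that one-parameter
    model; ``method="loglinear"`` fits a straight line to ``log(dff)`` over
    the positive samples and returns ``-1/slope``.

    When ``fit_end_index`` is omitted the window runs from the peak to the
    first sample below 5% of the peak, capped at 40 s.
    """
    y_all = np.asarray(dff, dtype=float)
    if not (0 <= peak_index < len(y_all)):
        raise IndexError("peak_index out of range")
    a = y_all[peak_index]
    if not (a > 0):
        raise ValueError("dff at the peak must be positive")
    if fit_end_index is None:
        fit_end_index = _default_fit_end(y_all, peak_index, fps)
    if fit_end_index <= peak_index:
        raise ValueError("fit window must extend past the peak")
    y = y_all[peak_index : fit_end_index + 1]
    if len(y) < 3 and method == "nls":
        raise ValueError("fit window must hold at least 3 samples")
    if len(y) < 2:
        raise ValueError("fit window must hold at least 2 samples")
    if (y[1:] <= 0).all():
        raise ValueError("decay segment is entirely non-positive; cannot fit")
    t = np.arange(len(y)) / fps

    if method == "loglinear":
        pos = y > 0
        slope, _ = np.polyfit(t[pos], np.log(y[pos]), 1)
        if slope >= 0:
            raise ValueError("decay segment is non-decaying; cannot fit")
        tau = -1.0 / slope
    elif method == "nls":
        # crude initial tau from time to fall below a/e, else window length
        below = np.nonzero(y < a / np.e)[0]
        tau0 = t[below[0]] if below.size else max(t[-1], 1.0 / fps)
        tau0 = max(tau0, 1e-3)
        popt, _ = curve_fit(
            lambda tt, tau: a * np.exp(-tt / tau), t, y,
            p0=[tau0], bounds=(1e-9, np.inf), maxfev=2000,
        )
        tau = float(popt[0])
    else:
        raise ValueError(f"unknown method {method!r}")

    rss = float(np.sum((y - a * np.exp(-t / tau)) ** 2))
    return DecayFit(
        dff_max=float(a), tau_s=float(tau),
        fit_window=(peak_index / fps, fit_end_index / fps),
        rss=rss, n_samples=len(y),
    )


def _window_indices(n: int, fps: float, window_s) -> np.ndarray:
    start, end = window_s
    if not (end > start):
        raise ValueError(f"window ({start}, {end}) is empty or reversed")
    k = np.arange(n)
    tt = k / fps
    return k[(tt >= start) & (tt < end)]


def summed_response(dff, fps: float, window_s) -> SummedResponse:
    """Sum of dF/F samples whose timestamps lie in ``[start, end)``."""
    y = np.asarray(dff, dtype=float)
    idx = _window_indices(len(y), fps, window_s)
    if idx.size == 0:
        raise ValueError(f"window {window_s} contains no samples at fps={fps}")
    return SummedResponse(float(y[idx].sum()), int(idx.size))


def changing_ratio(value_post: float, value_reference: float) -> float:
    """Post/reference ratio, e.g. the drug-condition sum over the pre-drug sum."""
    if value_reference == 0:
        raise ZeroDivisionError("changing ratio undefined for zero reference")
    return value_post / value_reference


def peak_response(dff, fps: float, search_window_s) -> tuple[float, float]:
    """Maximum dF/F within ``[start, end)`` and its time; ties -> earliest."""
    y = np.asarray(dff, dtype=float)
    idx = _window_indices(len(y), fps, search_window_s)
    if idx.size == 0:
        raise ValueError(f"window {search_window_s} contains no samples at fps={fps}")
    best = idx[int(np.argmax(y[idx]))]
    return float(y[best]), float(best / fps)


def detect_occurrence(
    dff, fps: float, stim_time_s: float,
    response_window_s: float = 5.0, k_sd: float = 3.0, baseline_s: float = 5.0,
) -> bool:
    """Did a transient occur after the stimulus?

    True iff the maximum dF/F within ``response_window_s`` after the stimulus
    strictly exceeds ``k_sd`` times the dF/F standard deviation over the
    ``baseline_s`` seconds preceding the stimulus.
    """
    y = np.asarray(dff, dtype=float)
    if stim_time_s < baseline_s:
        raise ValueError(
            f"need >= {baseline_s} s of pre-stimulus baseline; stimulus at {stim_time_s} s"
        )
    base_idx = _window_indices(len(y), fps, (stim_time_s - baseline_s, stim_time_s))
    if base_idx.size < 2:
        raise ValueError("insufficient pre-stimulus baseline samples")
    sd = float(np.std(y[base_idx], ddof=1))
    resp_idx = _window_indices(len(y), fps, (stim_time_s, stim_time_s + response_window_s))
    if resp_idx.size == 0:
        raise ValueError("response window contains no samples")
    return bool(y[resp_idx].max() > k_sd * sd)


def response_vector(
    dff_matrix, fps: float, stim_time_s: float,
    summary: str = "peak", window_s: float = 5.0,
) -> np.ndarray:
    """Per-cell response summary vector for one stimulus presentation.

    Element i summarizes cell i's dF/F within ``window_s`` after stimulus
    onset — the peak by default (matching the short, <5 s sensory transient
    kinetics), or the mean with ``summary="mean"``.  Cell order follows the
    matrix row order and must be held fixed across repetitions by the caller.
    """
    mat = np.atleast_2d(np.asarray(dff_matrix, dtype=float))
    idx = _window_indices(mat.shape[1], fps, (stim_time_s, stim_time_s + window_s))
    if idx.size == 0:
        raise ValueError("response window contains no samples")
    if summary == "peak":
        return mat[:, idx].max(axis=1)
    if summary == "mean":
        return mat[:, idx].mean(axis=1)
    raise ValueError(f"unknown summary {summary!r}")
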