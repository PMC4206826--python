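"""Movie-to-traces front end.

Rigid (translation-only) frame registration, semi-automatic cell detection on
the mean image, astrocyte exclusion via the red counterstain channel, and
mean-over-ROI trace extraction.  Coordinates are 0-based ``(row, col)`` =
``(cy, cx)``; a pixel belongs to a disk ROI iff its center distance is <= r.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.registration import phase_cross_correlation

from .synthetic import TraceMatrix, _shift_frame

__all__ = ["ROI", "ROISet", "Movie", "register_frames", "detect_cells",
           "classify_astrocytes", "extract_traces"]


@dataclass(frozen=True)
class ROI:
    """A disk region of interest."""

    id: int
    cx: float
    cy: float
    r: float
    label: str = "unknown"  # neuron | astrocyte | unknown

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.ogrid[:height, :width]
        return (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.r ** 2


@dataclass
class ROISet:
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("ROI ids must be unique")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def to_records(self) -> list[dict]:
        return [
            {"id": r.id, "cx": r.cx, "cy": r.cy, "r": r.r, "label": r.label}
            for r in self.rois
        ]

    @classmethod
    def from_records(cls, records) -> "ROISet":
        return cls([ROI(int(d["id"]), float(d["cx"]), float(d["cy"]),
                        float(d["r"]), d.get("label", "unknown")) for d in records])


@dataclass
class Movie:
    """Multi-channel movie: each channel is a T x H x W intensity array."""

    channels: dict
    fps: float

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.channels.items()}
        if not shapes:
            raise ValueError("movie needs at least one channel")
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if len(first) != 3 or min(first) < 1:
            raise ValueError("channels must be non-empty T x H x W arrays")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]


def register_frames(frames, reference_frame_index: int = 0):
    """Translation-only registration against a reference frame.

    Each frame is shifted by the integer translation that maximizes its
    cross-correlation with the reference (phase correlation, rounded to whole
    pixels); exposed borders are filled with the frame median.

    Accepts a bare ``T x H x W`` array or a :class:`Movie`; for a movie the
    shifts are estimated on the ``green`` (or first) channel and applied to
    all channels identically.

    Returns
    -------
    registered, shifts
        ``shifts`` is a ``T x 2`` integer array of (dx, dy) corrections
        applied to each frame (a frame drifted by +5 px in x reports -5).
    """
    if isinstance(frames, Movie):
        movie = frames
        key = "green" if "green" in movie.channels else next(iter(movie.channels))
        _, shifts = register_frames(np.asarray(movie.channels[key], float),
                                    reference_frame_index)
        out = {}
        for name, chan in movie.channels.items():
            chan = np.asarray(chan, float)
            reg = np.empty_like(chan)
            for f in range(chan.shape[0]):
                dx, dy = shifts[f]
                reg[f] = _shift_frame(chan[f], int(dy), int(dx), float(np.median(chan[f])))
            out[name] = reg
        return Movie(out, movie.fps), shifts

    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a non-empty T x H x W frame stack")
    if not (0 <= reference_frame_index < arr.shape[0]):
        raise IndexError("reference frame index out of range")
    ref = arr[reference_frame_index]
    T = arr.shape[0]
    shifts = np.zeros((T, 2), dtype=int)
    registered = np.empty_like(arr)
    for f in range(T):
        if f == reference_frame_index:
            registered[f] = arr[f]
            continue
        shift_yx, _, _ = phase_cross_correlation(ref, arr[f], upsample_factor=1)
        dy, dx = int(round(shift_yx[0])), int(round(shift_yx[1]))
        shifts[f] = (dx, dy)
        if (dy, dx) == (0, 0):
            registered[f] = arr[f]
        else:
            registered[f] = _shift_frame(arr[f], dy, dx, float(np.median(arr[f])))
    return registered, shifts


def detect_cells(
    mean_image,
    min_radius: float = 3.0,
    max_radius: float = 6.0,
    intensity_percentile: float = 80.0,
    seeds=None,
) -> ROISet:
    """Detect cell bodies on a mean image as fixed-radius disks.

    Automatic path: Gaussian smoothing, then local maxima above the given
    intensity percentile of the smoothed image, kept non-overlapping in order
    of decreasing peak intensity.  Semi-automatic path: when ``seeds`` (a list
    of (cx, cy) points) is supplied, exactly one ROI is returned per seed.
    """
    img = np.asarray(mean_image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("mean image must be finite")
    if max_radius < min_radius:
        raise ValueError("max_radius must be >= min_radius")
    radius = 0.5 * (min_radius + max_radius)

    if seeds is not None:
        return ROISet([
            ROI(i, float(cx), float(cy), radius) for i, (cx, cy) in enumerate(seeds)
        ])

    smoothed = gaussian(img, sigma=max(min_radius / 2.0, 0.5), preserve_range=True)
    if smoothed.max() <= smoothed.min():
        return ROISet([])
    threshold = np.percentile(smoothed, intensity_percentile)
    peaks = peak_local_max(
        smoothed,
        min_distance=max(int(np.ceil(min_radius)), 1),
        threshold_abs=threshold,
        exclude_border=False,
    )
    # peaks come sorted by descending intensity; greedily enforce non-overlap
    kept: list[tuple[float, float]] = []
    for (py, px) in peaks:
        if all((py - y) ** 2 + (px - x) ** 2 > (2 * radius) ** 2 for (y, x) in kept):
            kept.append((float(py), float(px)))
    return ROISet([ROI(i, cx, cy, radius) for i, (cy, cx) in enumerate(kept)])


def classify_astrocytes(
    rois: ROISet, red_mean_image, red_threshold_percentile: float = 75.0
) -> ROISet:
    """Label ROIs whose red-channel intensity marks them as astrocytes.

    An ROI is labeled ``astrocyte`` iff its mean red intensity strictly
    exceeds the given percentile of the ROI-wise red intensities; all other
    ROIs are labeled ``neuron``.
    """
    red = np.asarray(red_mean_image, dtype=float)
    if len(rois) == 0:
        return ROISet([])
    h, w = red.shape
    means = np.array([red[roi.mask(h, w)].mean() for roi in rois])
    threshold = np.percentile(means, red_threshold_percentile)
    labeled = [
        replace(roi, label="astrocyte" if m > threshold else "neuron")
        for roi, m in zip(rois, means)
    ]
    return ROISet(labeled)


def extract_traces(
    frames, rois: ROISet, fps: float = 2.3,
    exclude_astrocytes: bool = False, channel: str = "green", events=(),
) -> TraceMatrix:
    """Mean-over-ROI trace extraction.

    One row per retained ROI (input order preserved), each the per-frame mean
    intensity over the ROI's pixels.  With ``exclude_astrocytes`` ROIs labeled
    ``astrocyte`` are dropped.
    """
    if isinstance(frames, Movie):
        fps = frames.fps
        frames = frames.channels[channel]
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a T x H x W frame stack")
    T, h, w = arr.shape
    keep = [r for r in rois if not (exclude_astrocytes and r.label == "astrocyte")]
    data = np.empty((len(keep), T))
    flat = arr.reshape(T, -1)
    for i, roi in enumerate(keep):
        m = roi.mask(h, w).ravel()
        if not m.any():
            raise ValueError(f"ROI {roi.id} covers zero pixels")
        data[i] = flat[:, m].mean(axis=1)
    return TraceMatrix(
        data.reshape(len(keep), T), fps=fps, events=tuple(events),
        cell_ids=np.array([r.id for r in keep]),
    )
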