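"""Synthetic two-photon population calcium data with known ground truth.

Generates raw fluorescence traces, small two-channel movies and complete
multi-animal conditioning experiments that emulate dopamine-modulated
prefrontal population responses:

* **short** sensory-evoked transients (V2L stimulation) that rise within a
  frame or two and decay within ~5 s, and
* **long** dopaminergic transients (phasic VTA stimulation) that peak slowly,
  6–7 s after the stimulus, and last 20–30 s,

both riding on a baseline with slow drift and white photon-like noise.  All
injected amplitudes, kernels, occurrence flags and conditioning effects are
recorded in a :class:`GroundTruth` object so that downstream estimators can be
tested for parameter recovery.

Only ratios of fluorescence are meaningful; baseline units are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design import PARADIGMS, TIME_POINTS, ExperimentDesign

__all__ = [
    "StimulusEvent",
    "TransientKernel",
    "SimConfig",
    "MovieConfig",
    "GroundTruth",
    "TraceMatrix",
    "SimulatedExperiment",
    "SimulatedMovie",
    "make_transient_kernel",
    "simulate_trace",
    "simulate_experiment",
    "simulate_movie",
    "default_paradigm_effects",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class StimulusEvent:
    """A single electrical stimulation burst.

    ``site`` is ``"VTA"`` (dopaminergic midbrain input; phasic bursts of
    10–15 pulses at 40–50 Hz evoke the long transients) or ``"V2L"``
    (sensory cortical input; 5 pulses at 20 Hz evoke short transients).
    """

    time_s: float
    site: str
    frequency_hz: float = 50.0
    n_pulses: int = 10

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError("event time must be >= 0")
        if self.site not in ("VTA", "V2L"):
            raise ValueError(f"site must be 'VTA' or 'V2L', got {self.site!r}")
        if not (self.frequency_hz > 0):
            raise ValueError("frequency_hz must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")


@dataclass(frozen=True)
class TransientKernel:
    """Unit-peak sampled calcium transient shape.

    The kernel is defined on the frame grid ``t_k = k / fps``.  The requested
    peak time is snapped to the nearest frame; the rise up to the peak follows
    an alpha-like shape ``(t/t_peak) * exp(1 - t/t_peak)`` and the decay after
    the peak is exactly ``exp(-(t - t_peak)/tau_s)``, so the decay constant of
    every injected transient is known to the tests.
    """

    kind: str
    peak_time_s: float
    tau_s: float
    duration_s: float
    fps: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("kernel values must be non-negative")
        if not np.isclose(v.max(initial=0.0), 1.0):
            raise ValueError("kernel must be unit-normalized (max == 1)")
        if self.kind == "short":
            if self.peak_time_s > 1.5 or self.duration_s > 5.0:
                raise ValueError("short kernel requires peak_time_s <= 1.5 s and duration_s <= 5 s")
        elif self.kind == "long":
            if not (6.0 <= self.peak_time_s <= 7.0):
                raise ValueError("long kernel requires peak_time_s in [6, 7] s")
            if not (20.0 <= self.duration_s <= 30.0):
                raise ValueError("long kernel requires duration_s in [20, 30] s")
        else:
            raise ValueError(f"kind must be 'short' or 'long', got {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return len(self.values)


def make_transient_kernel(
    kind: str,
    peak_time_s: float | None = None,
    tau_s: float | None = None,
    fps: float = 2.3,
    duration_s: float | None = None,
) -> TransientKernel:
    """Build a unit-peak transient kernel sampled at ``fps``.

    Defaults per kind: short — peak 0.5 s, tau 1.2 s, support 5 s (decays to
    < 3% of peak by 5 s); long — peak 6.5 s, tau 8 s, support 30 s.

    Parameters
    ----------
    kind
        ``"short"`` (sensory-like) or ``"long"`` (dopaminergic-like).
    peak_time_s
        Requested time-to-peak from event onset; snapped to the nearest frame.
    tau_s
        Exponential decay constant after the peak.
    """
    defaults = {
        "short": dict(peak_time_s=0.5, tau_s=1.2, duration_s=5.0),
        "long": dict(peak_time_s=6.5, tau_s=8.0, duration_s=30.0),
    }
    if kind not in defaults:
        raise ValueError(f"kind must be 'short' or 'long', got {kind!r}")
    if not (fps > 0):
        raise ValueError("fps must be positive")
    peak_time_s = defaults[kind]["peak_time_s"] if peak_time_s is None else float(peak_time_s)
    tau_s = defaults[kind]["tau_s"] if tau_s is None else float(tau_s)
    duration_s = defaults[kind]["duration_s"] if duration_s is None else float(duration_s)
    if not (tau_s > 0):
        raise ValueError("tau_s must be positive")
    if peak_time_s < 0:
        raise ValueError("peak_time_s must be >= 0")

    # snap the peak to the frame grid so the sampled maximum is exactly 1
    t_peak = round(peak_time_s * fps) / fps
    n = int(np.floor(duration_s * fps)) + 1
    t = np.arange(n) / fps
    values = np.empty(n)
    if t_peak > 0:
        rise = t <= t_peak
        values[rise] = (t[rise] / t_peak) * np.exp(1.0 - t[rise] / t_peak)
        values[~rise] = np.exp(-(t[~rise] - t_peak) / tau_s)
    else:
        values = np.exp(-t / tau_s)
    return TransientKernel(
        kind=kind, peak_time_s=t_peak, tau_s=tau_s, duration_s=duration_s,
        fps=fps, values=values,
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration for a full conditioning experiment.

    The defaults encode the study conditions: 8 animals per paradigm group,
    50–80 cells per animal imaged at 2.3 Hz, three V2L stimulus repetitions
    per test time point, response amplitudes calibrated to sit mostly below a
    dF/F of 0.2 at baseline, and the T1 pairing raising both the response
    gain and the inter-repetition pattern consistency at the late test points.

    ``paradigm_effects[paradigm][time_point] = (gain, coupling)`` —
    ``gain`` multiplies every cell's latent response amplitude; ``coupling``
    in [0, 1] shrinks the per-repetition amplitude jitter
    (sd = ``rep_jitter_sd * (1 - coupling)``), so the expected cosine
    similarity between repetitions increases monotonically with it.

    ``drug_scalars`` multiplies the long-transient amplitude and decay tau,
    emulating pharmacology (e.g. a D1 antagonist halving the response and
    shortening the decay).
    """

    n_animals_per_paradigm: int = 8
    n_cells: int | tuple[int, int] = (50, 80)
    fps: float = 2.3
    duration_s: float = 80.0
    stim_times_s: tuple[float, ...] = (20.0, 40.0, 60.0)
    baseline_f0: float = 100.0
    noise_sd: float = 0.02           # fraction of baseline
    drift_amplitude: float = 0.01    # fraction of baseline
    drift_period_s: float = 90.0
    responder_fraction: float = 0.8
    amplitude_mean: float = 0.12     # dF/F units
    amplitude_sd: float = 0.05
    rep_jitter_sd: float = 0.08      # per-repetition amplitude sd at coupling 0
    paradigm_effects: Mapping[str, Mapping[str, tuple[float, float]]] | None = None
    drug_scalars: Mapping[str, float] = field(
        default_factory=lambda: {"amplitude": 1.0, "tau": 1.0}
    )
    vta_amplitude_mean: float = 0.3  # long-transient dF/F, independent of V2L gain
    vta_amplitude_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_paradigm < 1:
            raise ValueError("n_animals_per_paradigm must be >= 1")
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must be in [0, 1]")
        if isinstance(self.n_cells, tuple):
            lo, hi = self.n_cells
            if lo < 1 or hi < lo:
                raise ValueError("n_cells range must satisfy 1 <= lo <= hi")
        elif self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        eff = self.paradigm_effects
        if eff is not None:
            for par, per_tp in eff.items():
                for tp, (gain, coupling) in per_tp.items():
                    if not (0.0 <= coupling <= 1.0):
                        raise ValueError(
                            f"similarity coupling must be in [0, 1]; got {coupling} "
                            f"for {par}/{tp}"
                        )


def default_paradigm_effects(
    t1_gain_2hr: float = 1.5,
    t1_coupling_2hr: float = 0.8,
    baseline_coupling: float = 0.3,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Study-condition effect table.

    Only the T1 pairing modifies the response: full gain and coupling at
    2 hr, intermediate at 1 hr, a small early rise right after conditioning.
    The three control paradigms keep gain 1 and the baseline coupling
    throughout.
    """
    controls = {tp: (1.0, baseline_coupling) for tp in TIME_POINTS}
    mid_gain = 1.0 + (t1_gain_2hr - 1.0) / 2.0
    mid_coupling = baseline_coupling + (t1_coupling_2hr - baseline_coupling) / 2.0
    return {
        "V2L_only": dict(controls),
        "VTA_only": dict(controls),
        "T2": dict(controls),
        "T1": {
            "before": (1.0, baseline_coupling),
            "right_after": (1.0 + (t1_gain_2hr - 1.0) / 4.0, baseline_coupling),
            "1hr": (mid_gain, mid_coupling),
            "2hr": (t1_gain_2hr, t1_coupling_2hr),
        },
    }


def unity_paradigm_effects(coupling: float = 1.0) -> dict[str, dict[str, tuple[float, float]]]:
    """All gains 1 and a common coupling — the no-effect (null) condition."""
    return {p: {tp: (1.0, coupling) for tp in TIME_POINTS} for p in PARADIGMS}


@dataclass
class TraceMatrix:
    """Raw fluorescence, cells x frames, with stimulus annotations."""

    data: np.ndarray
    fps: float
    events: tuple[StimulusEvent, ...] = ()
    cell_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.data.shape[0])

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class GroundTruth:
    """Everything the generator injected, keyed by (paradigm, animal, time_point).

    ``amplitudes`` are per cell x repetition dF/F amplitudes actually applied;
    ``occurrence`` is True where the applied amplitude is > 0; ``latent``
    holds the per-time-point population vector before repetition jitter;
    ``effects`` records the (gain, coupling) applied per paradigm/time point;
    ``vta_amplitudes`` the per-animal long-transient amplitudes.
    """

    amplitudes: dict = field(default_factory=dict)
    occurrence: dict = field(default_factory=dict)
    latent: dict = field(default_factory=dict)
    base_amplitudes: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    vta_amplitudes: dict = field(default_factory=dict)
    kernel: TransientKernel | None = None
    vta_kernel: TransientKernel | None = None


@dataclass
class SimulatedExperiment:
    """Output of :func:`simulate_experiment`."""

    traces: dict  # (paradigm, animal, time_point) -> TraceMatrix, V2L test recordings
    vta_traces: dict  # (paradigm, animal) -> TraceMatrix, single phasic VTA recording
    ground_truth: GroundTruth
    design: ExperimentDesign
    config: SimConfig


# --------------------------------------------------------------------------- #
# trace simulation
# --------------------------------------------------------------------------- #

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trace(
    baseline_f0: float,
    events: Sequence[StimulusEvent],
    kernels: Sequence[TransientKernel],
    amplitudes: Sequence[float],
    duration_s: float,
    fps: float = 2.3,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    drift_period_s: float = 90.0,
    seed=0,
) -> np.ndarray:
    """Simulate one raw fluorescence trace.

    ``trace = f0 * (1 + drift(t) + sum_i a_i * k_i(t - t_i)) + noise`` with
    white Gaussian noise of sd ``noise_sd * f0`` and a sinusoidal slow drift
    of amplitude ``drift_amplitude * f0`` — noise and drift scale with the
    baseline so all dF/F quantities are invariant to the fluorescence scale.
    """
    if baseline_f0 <= 0:
        raise ValueError("baseline_f0 must be positive")
    if len(events) != len(kernels) or len(events) != len(amplitudes):
        raise ValueError("events, kernels and amplitudes must be aligned")
    n = int(np.floor(duration_s * fps)) + 1
    for ev in events:
        if ev.time_s >= duration_s:
            raise ValueError(f"event at {ev.time_s} s lies outside the {duration_s} s recording")
    t = np.arange(n) / fps
    signal = np.zeros(n)
    for ev, kern, amp in zip(events, kernels, amplitudes):
        i0 = int(round(ev.time_s * fps))
        i1 = min(n, i0 + kern.n_samples)
        signal[i0:i1] += amp * kern.values[: i1 - i0]
    drift = drift_amplitude * np.sin(2.0 * np.pi * t / drift_period_s)
    rng = _as_rng(seed)
    noise = rng.normal(0.0, noise_sd * baseline_f0, n) if noise_sd > 0 else 0.0
    return baseline_f0 * (1.0 + drift + signal) + noise


def _signal_matrix(
    amplitudes: np.ndarray, stim_indices: Sequence[int], kernel: TransientKernel, n_frames: int
) -> np.ndarray:
    """cells x frames sum of amplitude-scaled kernels (vectorized over cells)."""
    sig = np.zeros((amplitudes.shape[0], n_frames))
    for r, i0 in enumerate(stim_indices):
        i1 = min(n_frames, i0 + kernel.n_samples)
        sig[:, i0:i1] += amplitudes[:, r : r + 1] * kernel.values[None, : i1 - i0]
    return sig


# --------------------------------------------------------------------------- #
# full experiment
# --------------------------------------------------------------------------- #

def simulate_experiment(
    design: ExperimentDesign | None = None,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> SimulatedExperiment:
    """Simulate the full multi-animal conditioning experiment.

    For each animal the generator draws a fixed population of cells with base
    response amplitudes (a responder subset with non-negative Gaussian
    amplitudes).  At each test time point the latent population vector is the
    base vector times the paradigm's gain for that time point (deterministic),
    and each of the three V2L repetitions applies the latent vector plus
    Gaussian repetition jitter whose sd shrinks with the similarity-coupling
    parameter, clipped at zero.  A separate single phasic-VTA recording per
    animal carries long transients with amplitudes drawn independently of the
    V2L responses.
    """
    design = design or ExperimentDesign()
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    effects = config.paradigm_effects
    if effects is None:
        effects = default_paradigm_effects()
    for par in design.paradigms:
        if par not in effects:
            raise ValueError(f"paradigm_effects missing paradigm {par!r}")

    fps = config.fps
    n_frames = int(np.floor(config.duration_s * fps)) + 1
    if len(config.stim_times_s) != design.n_repetitions:
        raise ValueError("stim_times_s must supply one onset per repetition")
    stim_idx = [int(round(ts * fps)) for ts in config.stim_times_s]
    kernel = make_transient_kernel("short", fps=fps)
    vta_kernel = make_transient_kernel(
        "long",
        tau_s=8.0 * float(config.drug_scalars.get("tau", 1.0)),
        fps=fps,
    )
    vta_amp_scale = float(config.drug_scalars.get("amplitude", 1.0))
    vta_duration_s = 90.0
    vta_n_frames = int(np.floor(vta_duration_s * fps)) + 1
    vta_stim_s = 30.0
    vta_i0 = int(round(vta_stim_s * fps))

    events = tuple(
        StimulusEvent(ts, "V2L", frequency_hz=20.0, n_pulses=5) for ts in config.stim_times_s
    )
    vta_event = (StimulusEvent(vta_stim_s, "VTA", frequency_hz=50.0, n_pulses=10),)

    root = np.random.SeedSequence(seed)
    truth = GroundTruth(kernel=kernel, vta_kernel=vta_kernel)
    truth.effects = {
        par: dict(effects[par]) for par in design.paradigms
    }
    traces: dict = {}
    vta_traces: dict = {}

    t = np.arange(n_frames) / fps
    drift = config.drift_amplitude * np.sin(2.0 * np.pi * t / config.drift_period_s)
    t_vta = np.arange(vta_n_frames) / fps
    drift_vta = config.drift_amplitude * np.sin(2.0 * np.pi * t_vta / config.drift_period_s)

    for pi, par in enumerate(design.paradigms):
        for ai in range(config.n_animals_per_paradigm):
            rng = np.random.default_rng(root.spawn(1)[0])
            if isinstance(config.n_cells, tuple):
                n_cells = int(rng.integers(config.n_cells[0], config.n_cells[1] + 1))
            else:
                n_cells = int(config.n_cells)
            responder = rng.random(n_cells) < config.responder_fraction
            base = np.maximum(
                rng.normal(config.amplitude_mean, config.amplitude_sd, n_cells), 0.0
            )
            base = base * responder
            truth.base_amplitudes[(par, ai)] = base

            for tp in design.time_points:
                gain, coupling = effects[par][tp]
                latent = gain * base
                jitter_sd = config.rep_jitter_sd * (1.0 - coupling)
                if jitter_sd > 0:
                    amps = latent[:, None] + rng.normal(
                        0.0, jitter_sd, (n_cells, design.n_repetitions)
                    )
                    amps = np.maximum(amps, 0.0)
                else:
                    amps = np.tile(latent[:, None], (1, design.n_repetitions))
                truth.latent[(par, ai, tp)] = latent
                truth.amplitudes[(par, ai, tp)] = amps
                truth.occurrence[(par, ai, tp)] = amps > 0

                sig = _signal_matrix(amps, stim_idx, kernel, n_frames)
                raw = config.baseline_f0 * (1.0 + drift[None, :] + sig)
                if config.noise_sd > 0:
                    raw = raw + rng.normal(
                        0.0, config.noise_sd * config.baseline_f0, raw.shape
                    )
                traces[(par, ai, tp)] = TraceMatrix(
                    raw, fps=fps, events=events,
                    meta={"paradigm": par, "animal": ai, "time_point": tp},
                )

            # single phasic VTA recording per animal (long transients)
            vta_amps = vta_amp_scale * np.maximum(
                rng.normal(config.vta_amplitude_mean, config.vta_amplitude_sd, n_cells), 0.0
            )
            truth.vta_amplitudes[(par, ai)] = vta_amps
            sig = _signal_matrix(vta_amps[:, None], [vta_i0], vta_kernel, vta_n_frames)
            raw = config.baseline_f0 * (1.0 + drift_vta[None, :] + sig)
            if config.noise_sd > 0:
                raw = raw + rng.normal(
                    0.0, config.noise_sd * config.baseline_f0, raw.shape
                )
            vta_traces[(par, ai)] = TraceMatrix(
                raw, fps=fps, events=vta_event,
                meta={"paradigm": par, "animal": ai, "time_point": "conditioning"},
            )

    return SimulatedExperiment(
        traces=traces, vta_traces=vta_traces, ground_truth=truth,
        design=design, config=config,
    )


# --------------------------------------------------------------------------- #
# movies
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class MovieConfig:
    """Two-channel movie rendering parameters.

    Neurons are green disks whose mean intensity follows a simulated trace;
    astrocytes (the SR101-counterstained population to be excluded) are bright
    in the red channel and moderately bright but static in green.  A disk
    pixel belongs to a cell iff its center distance is <= the cell radius —
    the same membership rule the ROI extraction uses.
    """

    n_neurons: int = 10
    n_astrocytes: int = 3
    height: int = 96
    width: int = 96
    n_frames: int = 120
    fps: float = 2.3
    radius_px: float = 4.0
    baseline_f0: float = 100.0
    background: float = 20.0
    astro_green: float = 60.0
    astro_red: float = 150.0
    neuron_red: float = 12.0
    red_background: float = 8.0
    noise_sd: float = 0.0            # pixel noise, fraction of baseline_f0
    amplitude: float = 0.5           # transient dF/F amplitude for every neuron
    stim_times_s: tuple[float, ...] = (20.0,)
    drift_px: tuple[int, int] = (0, 0)   # (dy, dx) applied from drift_start_frame
    drift_start_frame: int | None = None

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("movie must be at least 64 x 64 pixels")


@dataclass
class SimulatedMovie:
    """Two-channel movie plus ROI/trace ground truth."""

    green: np.ndarray   # T x H x W, uint16
    red: np.ndarray     # T x H x W, uint16
    fps: float
    rois: list          # [{id, cx, cy, r, label}]
    neuron_traces: np.ndarray  # n_neurons x T, pre-quantization mean intensities
    events: tuple
    config: MovieConfig


def _place_disks(rng, n, h, w, r, min_sep, occupied, max_tries=2000):
    centers = list(occupied)
    out = []
    tries = 0
    while len(out) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping disks of radius {r} "
                f"in a {h}x{w} field after {max_tries} tries"
            )
        tries += 1
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep ** 2 for (y, x) in centers):
            centers.append((cy, cx))
            out.append((cy, cx))
    return out


def _disk_mask(h, w, cy, cx, r):
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def simulate_movie(config: MovieConfig | None = None, seed: int = 0) -> SimulatedMovie:
    """Render a two-channel movie with ground-truth ROIs.

    The green channel carries neuron activity (each neuron's disk pixels share
    the same simulated trace value per frame) plus static astrocyte disks;
    the red channel marks astrocytes.  Optional global rigid drift shifts both
    channels identically from ``drift_start_frame`` on.  Frames are quantized
    to uint16, so extracted traces match injected traces to within half a
    count.
    """
    config = config or MovieConfig()
    rng = np.random.default_rng(seed)
    h, w, T = config.height, config.width, config.n_frames
    r = config.radius_px
    min_sep = 2.0 * r + 3.0

    neuron_centers = _place_disks(rng, config.n_neurons, h, w, r, min_sep, [])
    astro_centers = _place_disks(rng, config.n_astrocytes, h, w, r, min_sep, neuron_centers)

    duration_s = T / config.fps
    # stimuli beyond the movie length are dropped (short registration fixtures)
    events = tuple(StimulusEvent(ts, "V2L") for ts in config.stim_times_s
                   if ts < duration_s)
    kernel = make_transient_kernel("short", fps=config.fps)
    neuron_traces = np.empty((config.n_neurons, T))
    for i in range(config.n_neurons):
        tr = simulate_trace(
            config.baseline_f0, events, [kernel] * len(events),
            [config.amplitude] * len(events), duration_s, config.fps,
            noise_sd=0.0, seed=rng,
        )
        neuron_traces[i] = tr[:T]

    green = np.full((T, h, w), config.background, dtype=float)
    red = np.full((T, h, w), config.red_background, dtype=float)
    for i, (cy, cx) in enumerate(neuron_centers):
        m = _disk_mask(h, w, cy, cx, r)
        green[:, m] = neuron_traces[i][:, None]
        red[:, m] = config.neuron_red
    for (cy, cx) in astro_centers:
        m = _disk_mask(h, w, cy, cx, r)
        green[:, m] = config.astro_green
        red[:, m] = config.astro_red

    if config.noise_sd > 0:
        sd = config.noise_sd * config.baseline_f0
        green += rng.normal(0.0, sd, green.shape)
        red += rng.normal(0.0, sd, red.shape)

    if config.drift_start_frame is not None and config.drift_px != (0, 0):
        dy, dx = config.drift_px
        for arr, fill in ((green, config.background), (red, config.red_background)):
            for f in range(config.drift_start_frame, T):
                arr[f] = _shift_frame(arr[f], dy, dx, fill)

    rois = (
        [
            {"id": i, "cx": float(cx), "cy": float(cy), "r": float(r), "label": "neuron"}
            for i, (cy, cx) in enumerate(neuron_centers)
        ]
        + [
            {
                "id": config.n_neurons + j,
                "cx": float(cx), "cy": float(cy), "r": float(r), "label": "astrocyte",
            }
            for j, (cy, cx) in enumerate(astro_centers)
        ]
    )
    to_u16 = lambda a: np.clip(np.rint(a), 0, 65535).astype(np.uint16)
    return SimulatedMovie(
        green=to_u16(green), red=to_u16(red), fps=config.fps, rois=rois,
        neuron_traces=neuron_traces, events=events, config=config,
    )


def _shift_frame(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Integer-shift a frame, filling exposed borders with ``fill``."""
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = frame[ys, xs]
    return out
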