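"""Experiment designs: conditioning paradigms and test-phase schedules.

The experiment has three phases.  In the pre-conditioning phase the sensory
pathway (V2L, secondary visual cortex lateral area) is stimulated three times
to obtain the baseline population response.  In the conditioning phase V2L and
VTA (ventral tegmental area, the dopaminergic input) are stimulated together
once per minute for 30 minutes, with a paradigm-specific relative timing:

* ``T1`` — V2L 0.5 s *before* the VTA burst (coincident pairing),
* ``T2`` — V2L 45 s *after* the VTA burst (temporal-separation control),
* ``V2L_only`` / ``VTA_only`` — single-pathway controls.

In the test phase the V2L stimulus is repeated three times at each of four
time points (before, right after, 1 hr after and 2 hr after conditioning) and
the population response is compared across time points and paradigms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PARADIGMS = ("V2L_only", "VTA_only", "T1", "T2")
TIME_POINTS = ("before", "right_after", "1hr", "2hr")

# V2L onset relative to the VTA burst during conditioning, seconds
_PARADIGM_OFFSETS = {"T1": -0.5, "T2": 45.0, "V2L_only": None, "VTA_only": None}


@dataclass(frozen=True)
class ExperimentDesign:
    """Conditioning paradigms, test time points and stimulus schedule.

    Parameters
    ----------
    paradigms
        Subset of :data:`PARADIGMS`; each paradigm is a separate group of
        animals (between-subjects factor).
    time_points
        Test time points relative to conditioning (within-subjects factor).
    n_repetitions
        V2L stimulus repetitions per test time point.  Pattern similarity is
        defined over exactly three repetitions.
    conditioning_interval_s, conditioning_n_events
        Paired-stimulation schedule during the conditioning phase
        (one pairing per minute for 30 minutes).
    """

    paradigms: tuple[str, ...] = PARADIGMS
    time_points: tuple[str, ...] = TIME_POINTS
    n_repetitions: int = 3
    conditioning_interval_s: float = 60.0
    conditioning_n_events: int = 30
    paradigm_offsets_s: dict = field(default_factory=lambda: dict(_PARADIGM_OFFSETS))

    def __post_init__(self) -> None:
        unknown = [p for p in self.paradigms if p not in PARADIGMS]
        if unknown:
            raise ValueError(f"unknown paradigm(s): {unknown}; expected subset of {PARADIGMS}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if len(self.paradigms) == 0 or len(self.time_points) == 0:
            raise ValueError("design needs at least one paradigm and one time point")
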