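"""Acquisition metadata and spectral-model primitives.

The pulse-acquire experiment modelled throughout the package is a train of
small-flip-angle excitations: one FID of ``n_points`` complex samples is
recorded every ``repetition_time`` seconds, for ``n_repetitions`` repetitions.
Each excitation reads out a signal proportional to ``sin(flip_angle)`` of the
current longitudinal magnetization and leaves ``cos(flip_angle)`` of it behind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "AcquisitionParams",
    "MetabolitePeakSpec",
    "DEFAULT_ACQUISITION",
    "C1_SHIFTS_HZ",
    "C2_SHIFTS_HZ",
    "peaks_from_shifts",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-acquire acquisition parameters.

    Defaults match a dynamic cardiac 13C protocol at 7 T: 60 ECG-gated spectra
    over one minute (TR 1 s), 5 degree excitation, 13 593 Hz sweep width and
    2048 complex points per FID.
    """

    repetition_time: float = 1.0       # s
    flip_angle_deg: float = 5.0        # degrees
    sweep_width: float = 13593.0       # Hz
    n_points: int = 2048               # complex samples per FID
    n_repetitions: int = 60
    reference_frequency_mhz: float = 75.03  # 13C Larmor frequency at 7 T

    def __post_init__(self) -> None:
        if not (self.repetition_time > 0 and math.isfinite(self.repetition_time)):
            raise ValidationError("repetition_time must be a positive finite number")
        # flip angle 0 is permitted as a degenerate no-readout setting so the
        # closed-system behaviour of the kinetic simulator can be exercised
        if not (0 <= self.flip_angle_deg < 90):
            raise ValidationError("flip_angle_deg must lie in [0, 90)")
        if not (self.sweep_width > 0 and math.isfinite(self.sweep_width)):
            raise ValidationError("sweep_width must be positive")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")

    @property
    def dwell_time(self) -> float:
        """Sampling interval within one FID, 1/sweep_width (s)."""
        return 1.0 / self.sweep_width

    @property
    def flip_angle_rad(self) -> float:
        return math.radians(self.flip_angle_deg)

    def sample_times(self) -> np.ndarray:
        """Time axis of a single FID (s), starting at 0."""
        return np.arange(self.n_points) / self.sweep_width

    def repetition_times(self) -> np.ndarray:
        """Time of each excitation relative to the first one (s)."""
        return np.arange(self.n_repetitions) * self.repetition_time


@dataclass(frozen=True)
class MetabolitePeakSpec:
    """Spectral model of one metabolite resonance: a damped complex sinusoid
    ``exp(i*phase) * exp((-pi*linewidth + 2j*pi*frequency_offset) * t)``.

    ``frequency_offset`` is in Hz relative to the pyruvate resonance;
    ``linewidth`` is the Lorentzian full width at half maximum in Hz.
    """

    name: str
    frequency_offset: float   # Hz, relative to pyruvate
    linewidth: float = 20.0   # Hz
    phase: float = 0.0        # rad

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("peak name must be non-empty")
        if not (self.linewidth > 0 and math.isfinite(self.linewidth)):
            raise ValidationError(f"linewidth of {self.name!r} must be positive")
        if not math.isfinite(self.frequency_offset):
            raise ValidationError(f"frequency_offset of {self.name!r} must be finite")


DEFAULT_ACQUISITION = AcquisitionParams()

# Chemical-shift tables (Hz offsets from the pyruvate resonance at 7 T).
# These are editable defaults; the quantification only requires that the
# simulator and the fitter agree on the same table.
C1_SHIFTS_HZ: dict[str, float] = {
    "pyruvate": 0.0,
    "lactate": 1000.0,
    "pyruvate_hydrate": 630.0,
    "alanine": 570.0,
    "bicarbonate": -1320.0,
    "co2": -6130.0,
}

# [2-13C]pyruvate run: downstream carbonyl resonances sit upfield of C2
# pyruvate (~207 ppm); offsets derived from standard 13C shift tables at
# 75 Hz/ppm.
C2_SHIFTS_HZ: dict[str, float] = {
    "pyruvate": 0.0,
    "acetylcarnitine": -2610.0,
    "citrate": -2115.0,
    "glutamate": -1940.0,
}


def peaks_from_shifts(
    shifts: dict[str, float],
    linewidth: float = 20.0,
    phase: float = 0.0,
    names: list[str] | None = None,
) -> list[MetabolitePeakSpec]:
    """Build peak specs for the given metabolites from a shift table."""
    if names is None:
        names = list(shifts)
    missing = [n for n in names if n not in shifts]
    if missing:
        raise ValidationError(f"no chemical shift configured for {missing}")
    if len(set(names)) != len(names):
        raise ValidationError("peak names must be unique")
    return [
        MetabolitePeakSpec(name=n, frequency_offset=shifts[n], linewidth=linewidth, phase=phase)
        for n in names
    ]
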