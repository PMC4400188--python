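"""Synthetic data generation: kinetic time courses, FID rendering, CINE area
tables and factorial cohort tables.

Every downstream stage of the package (spectral quantification, kinetic
fitting, volumetrics, statistics) can be exercised end-to-end on the output of
this module, with known ground truth and seeded reproducibility.

Kinetic model
-------------
Hyperpolarized [1-13C]pyruvate label exchange is modelled as unidirectional
first-order flux from the pyruvate pool into each downstream pool x
(lactate, alanine, bicarbonate, CO2), with a single effective decay rate per
pool that lumps longitudinal relaxation and any back-flux::

    dM_p/dt = u(t) - (rho_p + sum_x k_px) * M_p
    dM_x/dt = k_px * M_p - rho_x * M_x

``u(t)`` is the label arrival function (intravenous injection, ~10 s).  At
every excitation each pool is instantaneously depleted by ``cos(flip_angle)``;
the signal read out is proportional to ``sin(flip_angle)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams, MetabolitePeakSpec
from .errors import ValidationError
from .fid import FidSeries

__all__ = [
    "TrapezoidInput",
    "GammaVariateInput",
    "KineticGroundTruth",
    "simulate_kinetics",
    "render_fids",
    "noise_sd_for_peak_snr",
    "CineGeometry",
    "simulate_cine",
    "CohortSpec",
    "simulate_cohort",
    "default_cohort_spec",
]


# --------------------------------------------------------------------------
# injection input functions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrapezoidInput:
    """Trapezoidal label-arrival rate: linear ramp up over ``ramp`` seconds,
    plateau, and linear ramp down, spanning ``duration`` seconds in total."""

    start: float = 0.0
    duration: float = 10.0
    amplitude: float = 1.0
    ramp: float = 2.0

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValidationError("injection duration must be positive")
        if not (0 <= self.ramp <= self.duration / 2):
            raise ValidationError("ramp must lie in [0, duration/2]")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = t - self.start
        out = np.zeros_like(s)
        inside = (s >= 0) & (s <= self.duration)
        if self.ramp > 0:
            up = inside & (s < self.ramp)
            down = inside & (s > self.duration - self.ramp)
            flat = inside & ~up & ~down
            out[up] = self.amplitude * s[up] / self.ramp
            out[down] = self.amplitude * (self.duration - s[down]) / self.ramp
            out[flat] = self.amplitude
        else:
            out[inside] = self.amplitude
        return out


@dataclass(frozen=True)
class GammaVariateInput:
    """Gamma-variate arrival rate ``A * (s/tp)^alpha * exp(alpha*(1 - s/tp))``,
    a common smooth bolus shape; used to show the kinetic estimator does not
    depend on the simulator's injection shape."""

    start: float = 0.0
    amplitude: float = 1.0
    alpha: float = 2.5
    time_to_peak: float = 4.0

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = np.clip(t - self.start, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.amplitude * (s / self.time_to_peak) ** self.alpha * np.exp(
                self.alpha * (1.0 - s / self.time_to_peak)
            )
        return np.where(s > 0, out, 0.0)


# --------------------------------------------------------------------------
# kinetic ground truth and forward simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticGroundTruth:
    """Ground-truth rates for the forward simulation.

    ``k_px`` maps product name -> first-order label-flux rate out of pyruvate
    (s^-1).  ``rho_x`` maps product name -> effective signal decay rate
    (s^-1); products without an entry use ``rho_default``.  ``rho_p`` is the
    effective pyruvate decay rate.  ``co2_bicarbonate_ratio`` is the fraction
    of PDH-derived label observed as CO2 rather than bicarbonate (the two are
    in pH-dependent equilibrium in vivo).
    """

    k_px: dict[str, float] = field(
        default_factory=lambda: {"lactate": 0.025, "alanine": 0.008, "bicarbonate": 0.012}
    )
    rho_x: dict[str, float] = field(default_factory=dict)
    rho_p: float = 0.05
    rho_default: float = 1.0 / 30.0
    input_fn: TrapezoidInput | GammaVariateInput = field(default_factory=TrapezoidInput)
    co2_bicarbonate_ratio: float = 0.1
    initial_pyruvate: float = 0.0   # pyruvate magnetization already present at t=0

    # (injection normally starts at t=0 with an empty pyruvate pool; a nonzero
    # initial level supports steady-state test configurations)

    def __post_init__(self) -> None:
        rates = list(self.k_px.values()) + list(self.rho_x.values()) + [
            self.rho_p, self.rho_default, self.initial_pyruvate
        ]
        if not all(math.isfinite(r) and r >= 0 for r in rates):
            raise ValidationError("all kinetic rates must be finite and >= 0")
        if "pyruvate" in self.k_px:
            raise ValidationError("pyruvate is the source pool, not a product")
        if not (0.0 <= self.co2_bicarbonate_ratio <= 1.0):
            raise ValidationError("co2_bicarbonate_ratio must lie in [0, 1]")

    def rho_of(self, product: str) -> float:
        return self.rho_x.get(product, self.rho_default)

    def expanded_rates(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Product names with PDH label split into bicarbonate and CO2 pools.

        Returns ``(names, k, rho)`` where the bicarbonate rate is scaled by
        ``1 - co2_bicarbonate_ratio`` and a CO2 pool carrying the remaining
        fraction is appended (when the ratio is nonzero).
        """
        names: list[str] = []
        k: list[float] = []
        rho: list[float] = []
        for name, rate in self.k_px.items():
            if name == "bicarbonate" and self.co2_bicarbonate_ratio > 0:
                names.append("bicarbonate")
                k.append(rate * (1.0 - self.co2_bicarbonate_ratio))
                rho.append(self.rho_of("bicarbonate"))
            else:
                names.append(name)
                k.append(rate)
                rho.append(self.rho_of(name))
        if "bicarbonate" in self.k_px and self.co2_bicarbonate_ratio > 0:
            names.append("co2")
            k.append(self.k_px["bicarbonate"] * self.co2_bicarbonate_ratio)
            rho.append(self.rho_of("co2"))
        return names, np.asarray(k), np.asarray(rho)


def _rk4_step(state: np.ndarray, t: float, h: float, deriv) -> np.ndarray:
    k1 = deriv(t, state)
    k2 = deriv(t + h / 2, state + h / 2 * k1)
    k3 = deriv(t + h / 2, state + h / 2 * k2)
    k4 = deriv(t + h, state + h * k3)
    return state + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_kinetics(
    truth: KineticGroundTruth,
    acq: AcquisitionParams,
    n_substeps: int = 10,
) -> tuple[np.ndarray, list[str]]:
    """Integrate the kinetic model over the acquisition train.

    Returns ``(M, names)``: ``M[r, m]`` is the longitudinal magnetization of
    pool ``m`` immediately *before* excitation ``r`` (arbitrary units), and
    ``names`` lists the pools (pyruvate first).  Integration is fixed-step RK4
    with ``n_substeps`` steps per repetition interval; the cos(flip) depletion
    is applied to every pool at each excitation.  If the injection starts
    before the first excitation, the model is pre-integrated from the
    injection start with the same step size.
    """
    if n_substeps < 1:
        raise ValidationError("n_substeps must be >= 1")
    prod_names, k_arr, rho_arr = truth.expanded_rates()
    names = ["pyruvate"] + prod_names
    n_pools = len(names)
    k_total = float(k_arr.sum())

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        d = np.empty_like(y)
        d[0] = float(truth.input_fn(t)) - (truth.rho_p + k_total) * y[0]
        d[1:] = k_arr * y[0] - rho_arr * y[1:]
        return d

    h = acq.repetition_time / n_substeps
    state = np.zeros(n_pools)
    state[0] = truth.initial_pyruvate
    t = min(0.0, float(truth.input_fn.start))
    # pre-acquisition arrival
    while t < -1e-12:
        step = min(h, -t)
        state = _rk4_step(state, t, step, deriv)
        t += step
    t = 0.0

    cos_theta = math.cos(acq.flip_angle_rad)
    M = np.empty((acq.n_repetitions, n_pools))
    for r in range(acq.n_repetitions):
        M[r] = state
        state = state * cos_theta  # excitation depletes every pool
        if r < acq.n_repetitions - 1:
            for _ in range(n_substeps):
                state = _rk4_step(state, t, h, deriv)
                t += h
    if not np.all(np.isfinite(M)):
        raise ValidationError("kinetic simulation produced non-finite magnetization")
    return M, names


# --------------------------------------------------------------------------
# FID rendering
# --------------------------------------------------------------------------

def render_fids(
    magnetizations: np.ndarray,
    peaks: list[MetabolitePeakSpec],
    acq: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FidSeries:
    """Render per-repetition magnetizations into noisy complex FIDs.

    Each repetition's FID is the sum over metabolites of
    ``A * sin(flip) * exp(i*phase) * exp((-pi*lw + 2j*pi*offset) * t)``
    sampled at the dwell time, plus i.i.d. circular complex Gaussian noise of
    standard deviation ``noise_sd`` per real channel.
    """
    M = np.asarray(magnetizations, dtype=float)
    if M.ndim != 2:
        raise ValidationError("magnetizations must be 2-D (repetitions x metabolites)")
    if M.shape[0] != acq.n_repetitions:
        raise ValidationError(
            f"magnetizations have {M.shape[0]} repetitions, acquisition expects {acq.n_repetitions}"
        )
    if M.shape[1] != len(peaks):
        raise ValidationError(
            f"{M.shape[1]} metabolite columns but {len(peaks)} peak specs"
        )
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    t = acq.sample_times()
    basis = np.empty((len(peaks), acq.n_points), dtype=np.complex128)
    for i, p in enumerate(peaks):
        basis[i] = np.exp(1j * p.phase) * np.exp(
            (-math.pi * p.linewidth + 2j * math.pi * p.frequency_offset) * t
        )
    sin_theta = math.sin(acq.flip_angle_rad)
    data = (M * sin_theta) @ basis

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return FidSeries(
        data=data, acq=acq, metabolites=tuple(p.name for p in peaks), seed=seed
    )


def noise_sd_for_peak_snr(
    magnetizations: np.ndarray, acq: AcquisitionParams, snr: float, column: int = 0
) -> float:
    """Noise sd per channel giving the requested peak time-domain SNR for the
    given metabolite column (peak FID amplitude / noise sd)."""
    if snr <= 0:
        raise ValidationError("snr must be positive")
    peak_amp = float(np.max(magnetizations[:, column])) * math.sin(acq.flip_angle_rad)
    return peak_amp / snr


# --------------------------------------------------------------------------
# CINE area tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CineGeometry:
    """Idealized short-axis left-ventricle geometry.

    The cavity is a prolate-ellipsoid stack: slice ``s`` at axial position
    ``z_s`` has end-diastolic cavity area ``pi*r0^2*(1 - (z_s/L)^2)`` and a
    myocardial wall of constant cross-sectional area derived from
    ``wall_thickness_mm`` at the mid-slice.
    """

    cavity_radius_mm: float = 3.8        # mid-slice end-diastolic cavity radius
    wall_thickness_mm: float = 1.8
    length_fraction: float = 1.15        # half-length relative to stack half-extent


def simulate_cine(
    geometry: CineGeometry = CineGeometry(),
    contraction_fraction: float = 0.55,
    n_slices: int = 8,
    n_frames: int = 30,
    slice_thickness_mm: float = 1.6,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Generate a per-slice per-frame endo/epicardial area table.

    The endocardial area of every slice follows a smooth cyclic contraction
    ``A_s * (1 - c * w(f))`` with ``w(f) = (1 - cos(2*pi*f/n_frames)) / 2``,
    so frame 0 is end-diastole; the epicardial area is the endocardial area
    plus a constant (incompressible) wall area.  Optional Gaussian jitter of
    ``noise_sd`` mm^2 is added to the areas.

    Returns ``(table, truth)`` where ``truth`` holds the generator's own
    EDV/ESV/SV/EF and LV mass computed from the generated table.
    """
    if not (0.0 < contraction_fraction < 1.0):
        raise ValidationError("contraction_fraction must lie in (0, 1)")
    if n_slices < 1 or n_frames < 2:
        raise ValidationError("need n_slices >= 1 and n_frames >= 2")
    if slice_thickness_mm <= 0:
        raise ValidationError("slice_thickness_mm must be positive")
    if geometry.wall_thickness_mm < 0:
        raise ValidationError("wall thickness must be >= 0")

    rng = np.random.default_rng(seed)
    # axial slice positions, symmetric about the mid-ventricle
    half = n_slices * slice_thickness_mm / 2.0
    L = geometry.length_fraction * half
    z = (np.arange(n_slices) + 0.5) * slice_thickness_mm - half
    profile = np.clip(1.0 - (z / L) ** 2, 0.05, None)
    endo_ed = math.pi * geometry.cavity_radius_mm**2 * profile
    r_endo = np.sqrt(endo_ed / math.pi)
    wall_area = math.pi * ((r_endo + geometry.wall_thickness_mm) ** 2 - r_endo**2)

    frames = np.arange(n_frames)
    w = (1.0 - np.cos(2.0 * math.pi * frames / n_frames)) / 2.0
    endo = endo_ed[:, None] * (1.0 - contraction_fraction * w[None, :])
    epi = endo + wall_area[:, None]
    if noise_sd > 0:
        endo = np.clip(endo + noise_sd * rng.standard_normal(endo.shape), 0.0, None)
        epi = np.clip(epi + noise_sd * rng.standard_normal(epi.shape), endo, None)

    rows = []
    for s in range(n_slices):
        for f in range(n_frames):
            rows.append((s, f, endo[s, f], epi[s, f], slice_thickness_mm))
    table = pd.DataFrame(
        rows, columns=["slice", "frame", "endo_area_mm2", "epi_area_mm2", "thickness_mm"]
    )

    volumes = endo.sum(axis=0) * slice_thickness_mm  # mm^3 == uL
    ed, es = int(np.argmax(volumes)), int(np.argmin(volumes))
    edv, esv = float(volumes[ed]), float(volumes[es])
    lvm = float((epi[:, ed] - endo[:, ed]).sum() * slice_thickness_mm * 1.05)
    truth = {
        "edv_ul": edv,
        "esv_ul": esv,
        "sv_ul": edv - esv,
        "ef": (edv - esv) / edv if edv > 0 else float("nan"),
        "ed_frame": float(ed),
        "es_frame": float(es),
        "lv_mass_mg": lvm,
    }
    return table, truth


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Per-group sampling parameters for a factorial cohort.

    ``cells`` maps ``(surgery, diet, week, measure)`` -> ``(mean, sd, n)``.
    """

    cells: dict[tuple[str, str, int, str], tuple[float, float, int]]

    def __post_init__(self) -> None:
        for key, (mean, sd, n) in self.cells.items():
            if sd < 0:
                raise ValidationError(f"negative SD for cell {key}")
            if n < 2:
                raise ValidationError(f"cell {key} must have n >= 2")


def default_cohort_spec(measures: list[str] | None = None) -> CohortSpec:
    """Cohort spec parameterized from the published group summaries."""
    from . import table2

    cells: dict[tuple[str, str, int, str], tuple[float, float, int]] = {}
    for week in table2.WEEKS:
        for group in table2.GROUPS:
            n = table2.GROUP_NS[week][group]
            for measure, (mean, sd) in table2.GROUP_SUMMARIES[week][group].items():
                if measures is None or measure in measures:
                    cells[(group[0], group[1], week, measure)] = (mean, sd, n)
    return CohortSpec(cells)


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw per-animal values from Normal(mean, SD) per cell.

    Animal identifiers are stable within a (surgery, diet, week) group across
    measures, so each synthetic animal has one value per measure.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (surgery, diet, week, measure), (mean, sd, n) in sorted(spec.cells.items()):
        values = mean + sd * rng.standard_normal(n)
        for i, v in enumerate(values):
            rows.append((f"{surgery}-{diet}-w{week}-{i:02d}", surgery, diet, week, measure, v))
    return pd.DataFrame(
        rows, columns=["animal_id", "surgery", "diet", "week", "measure", "value"]
    )
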