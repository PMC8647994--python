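"""Synthetic dynamic FDG study generator.

Produces what a thoracic dynamic acquisition would measure, with known
ground truth:

* a plasma input function with a gamma-variate bolus peak blended into
  the monoexponential tail a + b exp(-c t) that real aortic curves
  follow from ~10 min onward;
* tumor time-activity curves from the irreversible two-tissue
  compartment model (K1, k2, k3, k4=0, blood fraction Vb), whose
  macro-parameter K1*k3/(k2+k3) is the ground-truth Patlak Ki;
* frame averaging over the acquisition schedules, optional
  count-statistics noise, 4D voxel phantoms, and whole cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .frames import (
    FramingSchedule,
    TimeActivityCurve,
    long_protocol_schedule,
    short_early_schedule,
    short_late_schedule,
)
from .input_function import BloodSample
from .kinetics import MonoexpParams

__all__ = [
    "DEFAULT_POPULATION_TAIL",
    "FINE_GRID_STEP_MIN",
    "InputSimParams",
    "TwoTissueParams",
    "PhantomGeometry",
    "CohortRanges",
    "SimulatedPatient",
    "fine_grid",
    "simulate_input",
    "simulate_tissue",
    "frame_average",
    "add_noise",
    "make_phantom",
    "simulate_cohort",
]

#: population plasma-tail coefficients (kBq/ml, kBq/ml, 1/min)
DEFAULT_POPULATION_TAIL = MonoexpParams(a=9.684, b=16.410, c=0.068)

#: 0.5-s step: every 5-s frame boundary falls exactly on the grid
FINE_GRID_STEP_MIN = 1.0 / 120.0


def fine_grid(t_end_min: float = 60.0, step_min: float = FINE_GRID_STEP_MIN) -> np.ndarray:
    n = int(round(t_end_min / step_min))
    return np.linspace(0.0, t_end_min, n + 1)


@dataclass(frozen=True)
class InputSimParams:
    """Plasma-input generator: gamma-variate bolus + monoexponential tail.

    Cp(t) = A (t/tp)^alpha e^{alpha (1 - t/tp)} + (1 - e^{-t/tau}) (a + b e^{-c t})

    The bolus peaks at exactly A kBq/ml at t = tp; the blend factor
    switches the tail on over ~tau minutes so that beyond 10 min the
    curve is the pure tail to better than 1%.
    """

    bolus_amplitude: float = 60.0
    bolus_peak_time: float = 0.6
    bolus_shape: float = 3.0
    tail: MonoexpParams = DEFAULT_POPULATION_TAIL
    blend_rate: float = 0.4

    def __post_init__(self) -> None:
        for name in ("bolus_amplitude", "bolus_peak_time", "bolus_shape", "blend_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bolus_peak_time >= 3.0:
            raise ValueError("bolus peak must occur before 3 min")


@dataclass(frozen=True)
class TwoTissueParams:
    """Irreversible two-tissue compartment rates (k4 = 0)."""

    K1: float  # ml/ml/min
    k2: float  # 1/min
    k3: float  # 1/min
    Vb: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.k2 <= 0 or self.k3 < 0:
            raise ValueError("require K1 > 0, k2 > 0, k3 >= 0")
        if not 0 <= self.Vb < 1:
            raise ValueError(f"blood fraction Vb must be in [0, 1), got {self.Vb}")

    @property
    def ki_true(self) -> float:
        """Macro influx constant K1 * k3 / (k2 + k3), the Patlak slope."""
        return self.K1 * self.k3 / (self.k2 + self.k3)


def simulate_input(p: InputSimParams, grid: np.ndarray) -> np.ndarray:
    """Plasma concentration on a fine time grid (min) starting at 0."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("fine grid must start at t = 0")
    if np.any(np.diff(grid) > 0.01 + 1e-12):
        raise ValueError("fine grid step must be <= 0.01 min")
    t = grid
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = t / p.bolus_peak_time
        bolus = p.bolus_amplitude * rel**p.bolus_shape * np.exp(
            p.bolus_shape * (1.0 - rel)
        )
    bolus[t == 0] = 0.0
    tail = (1.0 - np.exp(-t / p.blend_rate)) * (
        p.tail.a + p.tail.b * np.exp(-p.tail.c * t)
    )
    return bolus + tail


def simulate_tissue(
    cp_grid: np.ndarray, p: TwoTissueParams, grid: np.ndarray
) -> np.ndarray:
    """Tissue concentration CT = (1-Vb)(C1+C2) + Vb Cp on the fine grid.

    The free compartment obeys dC1/dt = K1 Cp - (k2+k3) C1 and the
    trapped one dC2/dt = k3 C1.  C1 is advanced with the exact
    exponential update for piecewise-linear Cp (no solver truncation
    error beyond the linear-in-Cp assumption per step); C2 by
    trapezoidal integration of k3 C1.
    """
    cp = np.asarray(cp_grid, dtype=float)
    t = np.asarray(grid, dtype=float)
    if cp.shape != t.shape:
        raise ValueError("cp_grid and grid must be aligned")
    beta = p.k2 + p.k3
    n = len(t)
    c1 = np.zeros(n)
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        e = np.exp(-beta * h)
        c0 = cp[i]
        m = (cp[i + 1] - cp[i]) / h
        # exact response of C1' = K1*(c0 + m u) - beta*C1 over the step
        c1[i + 1] = c1[i] * e + p.K1 * (
            c0 * (1.0 - e) / beta + m * (h / beta - (1.0 - e) / beta**2)
        )
    dt = np.diff(t)
    c2 = np.concatenate(([0.0], np.cumsum(p.k3 * 0.5 * (c1[1:] + c1[:-1]) * dt)))
    return (1.0 - p.Vb) * (c1 + c2) + p.Vb * cp


def frame_average(
    curve: np.ndarray,
    schedule: FramingSchedule,
    grid: np.ndarray,
    role: str = "tissue",
) -> TimeActivityCurve:
    """Average a fine-grid curve over each frame (trapezoid / duration)."""
    curve = np.asarray(curve, dtype=float)
    t = np.asarray(grid, dtype=float)
    vals = np.empty(len(schedule))
    for k, (a_s, b_s) in enumerate(schedule.frames):
        a, b = a_s / 60.0, b_s / 60.0
        if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
            raise ValueError(f"frame {k} [{a}, {b}] min outside the simulated grid")
        mask = (t >= a - 1e-12) & (t <= b + 1e-12)
        ts = t[mask]
        vs = curve[mask]
        if ts[0] > a + 1e-12:  # frame edge between grid points: interpolate
            ts = np.concatenate(([a], ts))
            vs = np.concatenate(([np.interp(a, t, curve)], vs))
        if ts[-1] < b - 1e-12:
            ts = np.concatenate((ts, [b]))
            vs = np.concatenate((vs, [np.interp(b, t, curve)]))
        vals[k] = np.trapezoid(vs, ts) / (b - a)
    return TimeActivityCurve(schedule=schedule, values=vals, role=role)


def add_noise(
    tac: TimeActivityCurve, noise_scale: float, seed: int | np.random.Generator
) -> TimeActivityCurve:
    """Gaussian frame noise with SD = noise_scale * sqrt(value / duration).

    Variance proportional to activity and inversely proportional to
    frame duration mimics count statistics after reconstruction.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0:
        return tac
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = noise_scale * np.sqrt(np.maximum(tac.values, 0.0) / tac.schedule.durations_min)
    noisy = tac.values + rng.normal(0.0, 1.0, size=len(tac.values)) * sd
    return replace(tac, values=noisy, raw=True)


# ---------------------------------------------------------------------------
# voxel phantom


@dataclass(frozen=True)
class PhantomGeometry:
    """Simple thorax stand-in: aortic cylinder + spherical tumor."""

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (3.18, 3.18, 3.0)
    aorta_center_xy: tuple[float, float] = (10.0, 16.0)
    aorta_radius_vox: float = 2.5
    aorta_slices: tuple[int, int] = (2, 14)  # half-open [lo, hi)
    tumor_center: tuple[float, float, float] = (22.0, 16.0, 8.0)
    tumor_radius_vox: float = 3.0
    background: float = 0.5
    blur_fwhm_mm: float | None = None

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        xi, yi, zi = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ax, ay = self.aorta_center_xy
        aorta = ((xi - ax) ** 2 + (yi - ay) ** 2 <= self.aorta_radius_vox**2) & (
            (zi >= self.aorta_slices[0]) & (zi < self.aorta_slices[1])
        )
        tx, ty, tz = self.tumor_center
        tumor = (xi - tx) ** 2 + (yi - ty) ** 2 + (zi - tz) ** 2 <= self.tumor_radius_vox**2
        if not aorta.any() or not tumor.any():
            raise ValueError("phantom region is empty on this grid")
        if (aorta & tumor).any():
            raise ValueError("aorta and tumor regions overlap")
        return aorta, tumor


def make_phantom(
    cp_tac: TimeActivityCurve,
    ct_tac: TimeActivityCurve,
    geom: PhantomGeometry,
    schedule: FramingSchedule | None = None,
):
    """4D phantom with aorta voxels = cp_tac, tumor voxels = ct_tac.

    Returns (DynamicImage, aorta_region, tumor_region); the regions are
    boolean 3D arrays suitable as VOI search regions.
    """
    from .voi import DynamicImage

    schedule = schedule or cp_tac.schedule
    if len(cp_tac.values) != len(schedule) or len(ct_tac.values) != len(schedule):
        raise ValueError("TAC lengths must match the schedule")
    aorta, tumor = geom.masks()
    nframes = len(schedule)
    vox = np.empty(geom.shape + (nframes,), dtype=float)
    for f in range(nframes):
        frame = np.full(geom.shape, geom.background, dtype=float)
        frame[aorta] = cp_tac.values[f]
        frame[tumor] = ct_tac.values[f]
        if geom.blur_fwhm_mm is not None:
            sigma_vox = [
                geom.blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
                for vs in geom.voxel_size_mm
            ]
            frame = ndimage.gaussian_filter(frame, sigma=sigma_vox)
        vox[..., f] = frame
    img = DynamicImage(voxels=vox, schedule=schedule, voxel_size_mm=geom.voxel_size_mm)
    return img, aorta, tumor


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for a simulated patient cohort.

    ``ki_range`` spans the influx constants seen clinically in NSCLC
    (about 0.01-0.13 1/min); K1 is derived per patient as
    Ki (k2+k3)/k3 so the cohort covers that span exactly.
    """

    ki_range: tuple[float, float] = (0.01, 0.13)
    k2_range: tuple[float, float] = (0.2, 0.6)
    k3_range: tuple[float, float] = (0.03, 0.09)
    vb_range: tuple[float, float] = (0.0, 0.0)
    bolus_amplitude_range: tuple[float, float] = (40.0, 80.0)
    tail_jitter: float = 0.0  # multiplicative lognormal-ish sd on (a, b)

    def __post_init__(self) -> None:
        for name in ("ki_range", "k2_range", "k3_range", "vb_range",
                     "bolus_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.tail_jitter < 0:
            raise ValueError("tail_jitter must be >= 0")


@dataclass(frozen=True)
class SimulatedPatient:
    """Ground truth plus everything the scanner would report."""

    truth: TwoTissueParams
    input_params: InputSimParams
    sample: BloodSample
    plasma_long: TimeActivityCurve | None = None
    tissue_long: TimeActivityCurve | None = None
    plasma_early: TimeActivityCurve | None = None
    tissue_early: TimeActivityCurve | None = None
    tissue_late: TimeActivityCurve | None = None


def simulate_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    protocol: str = "both",
    seed: int | np.random.Generator = 0,
    noise_scale: float = 0.0,
    tail: MonoexpParams = DEFAULT_POPULATION_TAIL,
) -> list[SimulatedPatient]:
    """Simulate ``n`` patients with known Ki under the chosen protocol.

    ``protocol``: "long" (single 60-min study), "short" (0-10-min and
    40-60-min acquisitions), or "both".  The blood sample is the true
    plasma value at 45 min.  Fixed seed gives a bit-identical cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if protocol not in ("long", "short", "both"):
        raise ValueError(f"unknown protocol {protocol!r}")
    ranges = ranges or CohortRanges()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = fine_grid(60.0)
    sched_long = long_protocol_schedule()
    sched_early = short_early_schedule()
    sched_late = short_late_schedule()

    patients: list[SimulatedPatient] = []
    for _ in range(n):
        ki = rng.uniform(*ranges.ki_range)
        k2 = rng.uniform(*ranges.k2_range)
        k3 = rng.uniform(*ranges.k3_range)
        vb = rng.uniform(*ranges.vb_range)
        truth = TwoTissueParams(K1=ki * (k2 + k3) / k3, k2=k2, k3=k3, Vb=vb)

        pat_tail = tail
        if ranges.tail_jitter > 0:
            fa, fb = np.exp(rng.normal(0.0, ranges.tail_jitter, size=2))
            pat_tail = MonoexpParams(a=tail.a * fa, b=tail.b * fb, c=tail.c)
        ip = InputSimParams(
            bolus_amplitude=rng.uniform(*ranges.bolus_amplitude_range),
            tail=pat_tail,
        )

        cp = simulate_input(ip, grid)
        ct = simulate_tissue(cp, truth, grid)
        sample = BloodSample(plasma_activity=float(np.interp(45.0, grid, cp)))

        def fa_tac(vals, sched, role):
            tac = frame_average(vals, sched, grid, role=role)
            return add_noise(tac, noise_scale, rng) if noise_scale > 0 else tac

        kwargs = {}
        if protocol in ("long", "both"):
            kwargs["plasma_long"] = fa_tac(cp, sched_long, "plasma")
            kwargs["tissue_long"] = fa_tac(ct, sched_long, "tissue")
        if protocol in ("short", "both"):
            kwargs["plasma_early"] = fa_tac(cp, sched_early, "plasma")
            kwargs["tissue_early"] = fa_tac(ct, sched_early, "tissue")
            kwargs["tissue_late"] = fa_tac(ct, sched_late, "tissue")
        patients.append(
            SimulatedPatient(truth=truth, input_params=ip, sample=sample, **kwargs)
        )
    return patients
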