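"""Core quantification math: Patlak graphical analysis, the
monoexponential plasma-tail model, and SUV.

The Patlak transform linearises irreversible-tracer kinetics: plotting

    y(t) = C_T(t) / C_p(t)   against   x(t) = (integral_0^t C_p) / C_p(t)

yields, once the free compartment has equilibrated, a straight line
whose slope is the net influx rate constant Ki (1/min) and whose
intercept is the distribution volume V_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .frames import TimeActivityCurve

if TYPE_CHECKING:  # pragma: no cover
    from .input_function import InputFunctionCurve

__all__ = [
    "MonoexpParams",
    "MonoexpFit",
    "PatlakResult",
    "SUVInputs",
    "monoexp_eval",
    "fit_monoexp",
    "select_frames_long",
    "select_frames_short",
    "patlak_transform",
    "patlak_fit",
    "patlak_ki",
    "suv",
    "DegenerateInputError",
    "FitFailureError",
]

#: lower bound used for the decay rate when it is unidentifiable (flat data)
C_LOWER_BOUND = 1e-6


class DegenerateInputError(ValueError):
    """Input values make the requested quantity undefined."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class MonoexpParams:
    """Coefficients of the plasma tail model Cp(t) = a + b * exp(-c * t).

    Units: ``a`` and ``b`` in kBq/ml, ``c`` in 1/min.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"decay rate c must be > 0, got {self.c}")
        if self.a < 0 or self.b < 0:
            raise ValueError(f"a and b must be >= 0, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class MonoexpFit:
    params: MonoexpParams
    residual_ss: float
    degenerate: bool = False


@dataclass(frozen=True)
class PatlakResult:
    """Patlak line estimate: slope Ki (1/min), intercept VD, fit r2."""

    Ki: float
    VD: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("Patlak fit needs at least 2 points")


@dataclass(frozen=True)
class SUVInputs:
    """Tumor activity at time T (kBq/ml), injected activity (MBq), weight (kg)."""

    ct_T: float
    A0: float
    bw: float

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError(f"injected activity must be > 0 MBq, got {self.A0}")
        if self.bw <= 0:
            raise ValueError(f"body weight must be > 0 kg, got {self.bw}")
        if self.ct_T < 0:
            raise ValueError(f"tissue activity must be >= 0, got {self.ct_T}")


def monoexp_eval(params: MonoexpParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate Cp(t) = a + b * exp(-c * t) at time ``t`` (minutes, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("monoexponential model is defined for t >= 0")
    out = params.a + params.b * np.exp(-params.c * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _monoexp(t, a, b, c):
    return a + b * np.exp(-c * t)


def fit_monoexp(
    times_min: Sequence[float],
    values: Sequence[float],
    max_restarts: int = 8,
) -> MonoexpFit:
    """Least-squares fit of a + b*exp(-c*t) to (times, values).

    Requires at least 4 strictly increasing time points with positive
    values.  Flat data (b unidentifiable) returns a degenerate fit with
    b = 0 and c at its lower bound.  Restarts from perturbed initial
    guesses before giving up.
    """
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.shape != t.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if len(t) < 4:
        raise ValueError(f"need at least 4 points to fit the tail model, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(v <= 0):
        raise ValueError("tail values must be positive")

    spread = np.ptp(v)
    if spread <= 1e-12 * max(1.0, np.max(np.abs(v))):
        params = MonoexpParams(a=float(np.mean(v)), b=0.0, c=C_LOWER_BOUND)
        rss = float(np.sum((v - params.a) ** 2))
        return MonoexpFit(params=params, residual_ss=rss, degenerate=True)

    a0 = float(v[-1])
    b0 = max(float(v[0] - a0), spread * 0.1)
    c0 = math.log(2.0) / max((t[-1] - t[0]) / 2.0, 1e-3)
    bounds = ([0.0, 0.0, C_LOWER_BOUND], [np.inf, np.inf, np.inf])

    rng = np.random.default_rng(0)
    best: tuple[float, np.ndarray] | None = None
    p0 = np.array([max(a0, 1e-9), b0, c0])
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = optimize.curve_fit(
                _monoexp, t, v, p0=p0, bounds=bounds, maxfev=20000
            )
            rss = float(np.sum((v - _monoexp(t, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
            if rss <= 1e-10 * float(np.sum(v**2)) or attempt >= 1:
                break
        except RuntimeError:
            pass
        # perturb the initial guess for the next attempt
        p0 = np.array([max(a0, 1e-9), b0, c0]) * rng.uniform(0.3, 3.0, size=3)
        p0 = np.maximum(p0, [0.0, 0.0, C_LOWER_BOUND])

    if best is None:
        raise FitFailureError(
            f"monoexponential fit did not converge after {max_restarts} restarts",
            best_residual=float("inf"),
        )
    rss, popt = best
    params = MonoexpParams(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]))
    return MonoexpFit(params=params, residual_ss=rss, degenerate=False)


# ---------------------------------------------------------------------------
# Patlak


def select_frames_long(
    tissue: TimeActivityCurve, t_start_min: float = 10.0
) -> list[int]:
    """Standard-protocol tissue frame selection: mid-times in (t_start, T].

    With the 60-min framing this keeps the ten 5-min frames with
    mid-times 12.5 ... 57.5 min.
    """
    mids = tissue.mid_times_min
    return [i for i, m in enumerate(mids) if m > t_start_min]


def select_frames_short(
    tissue: TimeActivityCurve,
    early_end_min: float = 10.0,
    late_window_min: tuple[float, float] = (40.0, 60.0),
) -> list[int]:
    """Short-protocol tissue frame selection.

    Keeps the last frame ending at ``early_end_min`` (the 5-10-min frame
    of the early acquisition, mid-time 7.5 min) plus every frame lying
    inside the late window: five points in the standard short framing.
    """
    sel: list[int] = []
    for i, (a, b) in enumerate(tissue.schedule.frames):
        a_min, b_min = a / 60.0, b / 60.0
        if abs(b_min - early_end_min) < 1e-9 and a_min < early_end_min:
            sel.append(i)
        elif a_min >= late_window_min[0] - 1e-9 and b_min <= late_window_min[1] + 1e-9:
            sel.append(i)
    return sel


def patlak_transform(
    input_curve: "InputFunctionCurve",
    tissue: TimeActivityCurve,
    selection: Sequence[int] | Callable[[TimeActivityCurve], Sequence[int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Patlak coordinates for the selected tissue frames.

    For each selected frame mid-time t:

        x = (integral_0^t Cp du) / Cp(t)    [min]
        y = C_T(t) / Cp(t)                  [dimensionless]

    ``selection`` is a list of frame indices, a callable producing one,
    or None for the standard long-protocol rule.
    """
    if not tissue.decay_corrected:
        raise ValueError("tissue TAC must be decay-corrected for Patlak analysis")
    tissue = tissue.clamped_nonnegative()

    if selection is None:
        idx = select_frames_long(tissue)
    elif callable(selection):
        idx = list(selection(tissue))
    else:
        idx = list(selection)
    if len(idx) < 2:
        raise ValueError(f"frame selection produced {len(idx)} frame(s); need >= 2")

    mids = tissue.mid_times_min[idx]
    ct = tissue.values[idx]
    cp = np.asarray(input_curve.evaluate(mids), dtype=float)
    for k, (t_k, cp_k) in enumerate(zip(mids, cp)):
        if cp_k <= 0:
            raise DegenerateInputError(
                f"input function is {cp_k:g} kBq/ml at selected frame "
                f"mid-time {t_k:g} min (frame index {idx[k]})"
            )
    auc = np.array([input_curve.integrate(t) for t in mids])
    x = auc / cp
    y = ct / cp
    return x, y


def patlak_fit(x: Sequence[float], y: Sequence[float]) -> PatlakResult:
    """Unweighted OLS line through the Patlak points: Ki = slope, VD = intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 (x, y) Patlak points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all Patlak x values identical; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if len(x) > 2 or not np.isnan(res.rvalue) else 1.0
    # collinear input gives rvalue = +/-1 exactly up to fp noise; clip
    r2 = min(max(r2, 0.0), 1.0)
    return PatlakResult(
        Ki=float(res.slope), VD=float(res.intercept), r2=r2, n_points=len(x)
    )


def patlak_ki(
    input_curve: "InputFunctionCurve",
    tissue: TimeActivityCurve,
    selection: Sequence[int] | Callable[[TimeActivityCurve], Sequence[int]] | None = None,
) -> PatlakResult:
    """Convenience pipeline: transform then fit."""
    x, y = patlak_transform(input_curve, tissue, selection)
    return patlak_fit(x, y)


def suv(inputs: SUVInputs) -> float:
    """Standardized uptake value, assuming tissue density 1 g/ml.

    SUV = C_T(T) [kBq/ml] / (A0 [MBq] / bw [kg]); the MBq/kg
    denominator is numerically kBq/g, so the ratio is dimensionless.
    """
    return inputs.ct_T / (inputs.A0 / inputs.bw)
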