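"""Input-function construction for regional Patlak analysis.

Three flavours of plasma curve are built here:

* the standard image-derived input function (IDIF): the full measured
  aorta TAC, rescaled so that its value at the venous-sample time
  equals the plasma activity measured in the sample;
* the population tail model (pIDIF): a monoexponential
  a + b * exp(-c t) fitted per patient over the 10-60-min tail, with
  coefficients averaged arithmetically across a training cohort;
* the hybrid short-protocol curve: measured 0-10-min segment followed
  by the population tail, again rescaled through the venous sample.

The venous blood sample anchors the absolute scale of every curve and
sidesteps partial-volume and spill-over bias in the aorta VOI signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .frames import TimeActivityCurve
from .kinetics import (
    DegenerateInputError,
    MonoexpFit,
    MonoexpParams,
    fit_monoexp,
    monoexp_eval,
)

__all__ = [
    "BloodSample",
    "InputFunctionCurve",
    "scale_to_blood_sample",
    "build_idif",
    "fit_population_tail",
    "build_hybrid_input",
    "integrate_input",
    "loocv_population",
]


@dataclass(frozen=True)
class BloodSample:
    """Venous plasma activity (kBq/ml in 1 ml plasma) drawn at ``t_sample`` min."""

    plasma_activity: float
    t_sample: float = 45.0

    def __post_init__(self) -> None:
        if self.plasma_activity <= 0:
            raise ValueError(f"plasma activity must be > 0, got {self.plasma_activity}")
        if not (10.0 <= self.t_sample <= 60.0):
            raise ValueError(
                f"sample time {self.t_sample} min outside the modelled tail (10-60 min)"
            )


@dataclass(frozen=True)
class InputFunctionCurve:
    """Composite plasma curve: measured early segment, optional analytic tail.

    value(t) = scale * (early interpolation    for t <= t_split
                        a + b exp(-c t)        for t >  t_split)

    With no tail, the early segment must itself cover [0, t_end].
    """

    early_segment: TimeActivityCurve
    tail: MonoexpParams | None = None
    t_split: float = 10.0
    t_end: float = 60.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.early_segment.role != "plasma":
            raise ValueError("early segment must be a plasma-role TAC")
        if self.tail is not None and not self.t_split < self.t_end:
            raise ValueError("t_split must be < t_end when an analytic tail is present")
        last_mid = self.early_segment.mid_times_min[-1]
        if self.tail is not None and last_mid > self.t_split + 1e-9:
            raise ValueError(
                f"measured early segment extends to {last_mid:g} min, beyond "
                f"the analytic-tail split at {self.t_split:g} min"
            )

    def evaluate(self, t_min: float | np.ndarray) -> np.ndarray:
        """Scaled plasma value at ``t_min`` (minutes in [0, t_end])."""
        t = np.atleast_1d(np.asarray(t_min, dtype=float))
        if np.any(t < 0) or np.any(t > self.t_end + 1e-9):
            raise ValueError(f"evaluation time outside [0, {self.t_end}] min")
        out = np.empty_like(t)
        early = t <= self.t_split + 1e-12 if self.tail is not None else np.ones_like(t, bool)
        out[early] = self.early_segment.interp(t[early])
        if self.tail is not None:
            out[~early] = monoexp_eval(self.tail, t[~early])
        return self.scale * out

    def integrate(self, T: float) -> float:
        return integrate_input(self, T)

    def tail_discontinuity(self) -> float:
        """|measured value - tail value| at t_split (diagnostic, scaled units)."""
        if self.tail is None:
            return 0.0
        early = self.scale * float(self.early_segment.interp(self.t_split))
        tail = self.scale * float(monoexp_eval(self.tail, self.t_split))
        return abs(early - tail)


def scale_to_blood_sample(
    curve: InputFunctionCurve, sample: BloodSample
) -> InputFunctionCurve:
    """Rescale the whole curve so curve(t_sample) equals the plasma sample.

    The factor s = plasma_activity / curve(t_sample) multiplies the
    early segment and the tail uniformly, so the operation is
    idempotent.
    """
    current = float(curve.evaluate(sample.t_sample)[0])
    if current <= 0:
        raise DegenerateInputError(
            f"input curve is {current:g} at the sample time {sample.t_sample} min"
        )
    s = sample.plasma_activity / current
    return replace(curve, scale=curve.scale * s)


def build_idif(
    aorta_tac: TimeActivityCurve, sample: BloodSample
) -> InputFunctionCurve:
    """Standard IDIF: full measured aorta TAC anchored to the blood sample."""
    t_end = aorta_tac.schedule.end_time_min
    if t_end < sample.t_sample:
        raise ValueError(
            f"aorta TAC ends at {t_end:g} min, before the {sample.t_sample:g}-min sample"
        )
    if aorta_tac.role != "plasma":
        aorta_tac = replace(aorta_tac, role="plasma")
    curve = InputFunctionCurve(
        early_segment=aorta_tac, tail=None, t_split=t_end, t_end=t_end
    )
    return scale_to_blood_sample(curve, sample)


def fit_population_tail(
    cohort: Sequence[InputFunctionCurve | TimeActivityCurve],
    tail_window: tuple[float, float] = (10.0, 60.0),
) -> tuple[MonoexpParams, list[MonoexpFit]]:
    """Population tail model: per-patient monoexponential fits, averaged.

    Each cohort entry is an unscaled IDIF (or plasma TAC); its frames
    with mid-times inside ``tail_window`` are fitted with
    a + b exp(-c t), and the population coefficients are the arithmetic
    means of the per-patient (a, b, c).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    lo, hi = tail_window
    fits: list[MonoexpFit] = []
    for k, entry in enumerate(cohort):
        tac = entry.early_segment if isinstance(entry, InputFunctionCurve) else entry
        scale = entry.scale if isinstance(entry, InputFunctionCurve) else 1.0
        mids = tac.mid_times_min
        mask = (mids >= lo) & (mids <= hi)
        if int(mask.sum()) < 4:
            raise ValueError(
                f"cohort entry {k}: only {int(mask.sum())} frame(s) inside the "
                f"tail window {tail_window}; need >= 4"
            )
        try:
            fits.append(fit_monoexp(mids[mask], scale * tac.values[mask]))
        except Exception as exc:
            raise RuntimeError(f"tail fit failed for cohort entry {k}: {exc}") from exc
    a = float(np.mean([f.params.a for f in fits]))
    b = float(np.mean([f.params.b for f in fits]))
    c = float(np.mean([f.params.c for f in fits]))
    return MonoexpParams(a=a, b=b, c=c), fits


def build_hybrid_input(
    early_tac: TimeActivityCurve,
    pop: MonoexpParams,
    sample: BloodSample,
    t_split: float = 10.0,
    t_end: float = 60.0,
) -> InputFunctionCurve:
    """Short-protocol input: measured 0-10-min segment + population tail,
    uniformly rescaled to pass through the blood sample."""
    if early_tac.role != "plasma":
        early_tac = replace(early_tac, role="plasma")
    curve = InputFunctionCurve(
        early_segment=early_tac, tail=pop, t_split=t_split, t_end=t_end
    )
    return scale_to_blood_sample(curve, sample)


def integrate_input(curve: InputFunctionCurve, T: float) -> float:
    """Area under the scaled input curve from 0 to T (kBq*min/ml).

    Trapezoidal over the measured early segment (linear rise from 0 at
    t = 0 to the first frame mid-time), closed form for the analytic
    tail: a (T - t1) + (b/c) (e^{-c t1} - e^{-c T}).
    """
    if T < 0 or T > curve.t_end + 1e-9:
        raise ValueError(f"integration limit {T} outside [0, {curve.t_end}] min")
    if T == 0:
        return 0.0
    tail_start = curve.t_split if curve.tail is not None else curve.t_end
    t_early_hi = min(T, tail_start)

    tac = curve.early_segment
    mids = tac.mid_times_min
    knots = np.concatenate(([0.0], mids)) if mids[0] > 0 else mids
    vals = np.concatenate(([0.0], tac.values)) if mids[0] > 0 else tac.values
    # clip the piecewise-linear knot set to [0, t_early_hi]
    inside = knots < t_early_hi
    xs = np.concatenate((knots[inside], [t_early_hi]))
    ys = np.concatenate((vals[inside], tac.interp(t_early_hi)[None]))
    auc = float(np.trapezoid(ys, xs))

    if curve.tail is not None and T > tail_start:
        a, b, c = curve.tail.a, curve.tail.b, curve.tail.c
        auc += a * (T - tail_start) + (b / c) * (
            np.exp(-c * tail_start) - np.exp(-c * T)
        )
    return curve.scale * auc


def loocv_population(
    cohort: Sequence[tuple[InputFunctionCurve, BloodSample]],
    tail_window: tuple[float, float] = (10.0, 60.0),
) -> tuple[list[float], float]:
    """Leave-one-out cross-validation of the population tail model.

    For each held-out patient the population coefficients are refitted
    on the remaining cohort, the patient's hybrid curve is rebuilt from
    their measured 0-10-min segment plus their blood sample, and the
    mean square percentage error (MSEP) against their full
    blood-sample-scaled IDIF is evaluated at the tail frame mid-times.
    Returns (per-patient MSEP %, mean MSEP %).
    """
    from .method_stats import msep

    if len(cohort) < 3:
        raise ValueError(f"LOOCV needs a cohort of >= 3, got {len(cohort)}")
    t_split = tail_window[0]
    errors: list[float] = []
    for k, (idif, sample) in enumerate(cohort):
        rest = [c for j, (c, _) in enumerate(cohort) if j != k]
        pop, _ = fit_population_tail(rest, tail_window)

        tac = idif.early_segment
        mids = tac.mid_times_min
        early_mask = mids <= t_split
        early = tac.select_frames(list(np.flatnonzero(early_mask)))
        hybrid = build_hybrid_input(
            early, pop, sample, t_split=t_split, t_end=tail_window[1]
        )

        reference = scale_to_blood_sample(idif, sample)
        tail_mids = mids[mids > t_split]
        ref_vals = reference.evaluate(tail_mids)
        fit_vals = hybrid.evaluate(tail_mids)
        errors.append(msep(ref_vals, fit_vals))
    return errors, float(np.mean(errors))
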