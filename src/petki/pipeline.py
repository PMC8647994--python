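"""End-to-end Ki estimation pipelines.

``ki_standard`` is the reference analysis: full 60-min IDIF and the
ten late tissue frames.  ``ki_short`` is the short-protocol analysis:
hybrid input (measured 0-10 min + population tail, blood-sample
scaled) and five tissue points (the 5-10-min frame plus the four
40-60-min frames).
"""

from __future__ import annotations

import numpy as np

from .frames import FramingSchedule, TimeActivityCurve
from .input_function import BloodSample, build_hybrid_input, build_idif
from .kinetics import (
    MonoexpParams,
    PatlakResult,
    patlak_ki,
    select_frames_long,
    select_frames_short,
)

__all__ = ["ki_standard", "ki_short", "merge_tissue_tacs"]


def ki_standard(
    aorta_tac: TimeActivityCurve,
    tissue_tac: TimeActivityCurve,
    sample: BloodSample,
) -> PatlakResult:
    """Standard-protocol Ki: measured IDIF (0-60 min), tissue 10-60 min."""
    idif = build_idif(aorta_tac, sample)
    return patlak_ki(idif, tissue_tac, select_frames_long)


def merge_tissue_tacs(
    early: TimeActivityCurve, late: TimeActivityCurve
) -> TimeActivityCurve:
    """Concatenate the early and late short-acquisition tissue TACs."""
    if early.schedule.frames[-1][1] > late.schedule.frames[0][0] + 1e-9:
        raise ValueError("early acquisition overlaps the late one")
    schedule = FramingSchedule(early.schedule.frames + late.schedule.frames)
    return TimeActivityCurve(
        schedule=schedule,
        values=np.concatenate([early.values, late.values]),
        role="tissue",
        decay_corrected=early.decay_corrected and late.decay_corrected,
        raw=early.raw or late.raw,
    )


def ki_short(
    plasma_early: TimeActivityCurve,
    tissue_early: TimeActivityCurve,
    tissue_late: TimeActivityCurve,
    pop: MonoexpParams,
    sample: BloodSample,
) -> PatlakResult:
    """Short-protocol Ki,s from the two short acquisitions."""
    hybrid = build_hybrid_input(plasma_early, pop, sample)
    tissue = merge_tissue_tacs(tissue_early, tissue_late)
    return patlak_ki(hybrid, tissue, select_frames_short)
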