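"""Small quantification formulas: blot arithmetic, colony percent-of-control,
and caliper-based tumor volume."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class BlotQuant:
    """Densitometry readings for one sample (total and phospho signal)."""

    sample_id: str
    total_signal: float
    phospho_signal: float
    reference_id: str

    def __post_init__(self) -> None:
        for name, v in (("total", self.total_signal), ("phospho", self.phospho_signal)):
            if not math.isfinite(v) or v < 0:
                raise AnalysisError(
                    f"sample {self.sample_id!r}: {name} signal must be finite and >= 0"
                )


@dataclass
class CaliperMeasure:
    """Caliper length/width in mm, canonicalized so width <= length."""

    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise AnalysisError("caliper dimensions must be positive")
        if self.width_mm > self.length_mm:
            self.length_mm, self.width_mm = self.width_mm, self.length_mm


def activated_signal(quants: Sequence[BlotQuant]) -> dict[str, float]:
    """Activated signal = total - phospho, clamped at 0, reference scaled to 100.

    The reference sample (named by each record's ``reference_id``, which must
    agree across records) is rescaled so its activated value is 100; all
    samples scale by the same factor, so uniform rescaling of the raw
    densitometry cancels out.
    """
    if not quants:
        raise AnalysisError("no blot quantifications supplied")
    refs = {q.reference_id for q in quants}
    if len(refs) != 1:
        raise AnalysisError(f"conflicting reference ids: {sorted(refs)}")
    ref_id = refs.pop()
    by_id = {q.sample_id: q for q in quants}
    if ref_id not in by_id:
        raise AnalysisError(f"reference sample {ref_id!r} not among quantifications")
    raw = {}
    for q in quants:
        value = q.total_signal - q.phospho_signal
        if value < 0:
            logger.info("sample %s: negative activated signal set to 0", q.sample_id)
            value = 0.0
        raw[q.sample_id] = value
    if raw[ref_id] == 0:
        raise AnalysisError(f"unscalable reference: activated signal of {ref_id!r} is 0")
    scale = 100.0 / raw[ref_id]
    return {sid: v * scale for sid, v in raw.items()}


def phospho_ratio_change(treated: BlotQuant, untreated: BlotQuant) -> float:
    """(phospho/total of treated) relative to (phospho/total of untreated)."""
    if treated.total_signal == 0 or untreated.total_signal == 0:
        raise AnalysisError("total signal must be nonzero for a phospho ratio")
    ratio_u = untreated.phospho_signal / untreated.total_signal
    if ratio_u == 0:
        raise AnalysisError("untreated phospho ratio is zero; change undefined")
    ratio_t = treated.phospho_signal / treated.total_signal
    return ratio_t / ratio_u


def percent_of_control(od_treated: float, od_control: float) -> float:
    """100 * treated / control from OD570-style readings."""
    if od_control <= 0:
        raise AnalysisError("control OD must be positive")
    if od_treated < 0:
        raise AnalysisError("treated OD must be non-negative")
    return 100.0 * od_treated / od_control


def summarize_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample sd (n-1) of replicate measurements."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise AnalysisError("replicate summary needs >= 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def tumor_volume(measure: CaliperMeasure) -> float:
    """Tumor volume in mm^3: 0.5 * length * width^2."""
    return 0.5 * measure.length_mm * measure.width_mm**2
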