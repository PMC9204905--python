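"""Relative quantification for methylation-specific and RT qPCR.

Quantification follows the comparative-Cq model: with amplification
efficiency E per cycle, a target present at relative abundance r against a
reference assay satisfies

    r = E ** (Cq_reference - Cq_target)

For QMSP the reference is ACTB and the level is the methylated-target /
ACTB ratio; for expression the reference is GAPDH.  Calibrating a tumor
level against its paired-normal level gives the fold change used by the
calling rules: hypermethylated at >= 2-fold, low expression at <= 0.5-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QpcrMeasurement",
    "RelativeLevel",
    "TreatmentEffect",
    "ReferenceFailureError",
    "relative_level",
    "calibrated_fold",
    "call_hypermethylation_qmsp",
    "call_low_expression",
    "treatment_effect",
]

#: Sentinel cycle count meaning "no amplification" (instrument runs 50 cycles).
MAX_CYCLES_DEFAULT = 50.0


class ReferenceFailureError(ValueError):
    """Reference assay failed to amplify: the sample cannot be normalised."""


@dataclass
class QpcrMeasurement:
    """Replicate Cq values for one sample's target and reference assays."""

    sample_id: str
    target: str
    reference: str
    target_cq: np.ndarray
    reference_cq: np.ndarray
    max_cycles: float = MAX_CYCLES_DEFAULT

    def __post_init__(self) -> None:
        self.target_cq = np.atleast_1d(np.asarray(self.target_cq, dtype=float))
        self.reference_cq = np.atleast_1d(np.asarray(self.reference_cq, dtype=float))
        for arr, name in ((self.target_cq, "target"), (self.reference_cq, "reference")):
            if arr.size == 0:
                raise ValueError(f"{name} needs at least one replicate")
            if np.any(arr <= 0) or np.any(arr > self.max_cycles):
                raise ValueError(f"{name} Cq must lie in (0, {self.max_cycles}]")


@dataclass
class RelativeLevel:
    """Normalized target/reference ratio for one sample."""

    sample_id: str
    level: float
    detected: bool = True
    calibrated_ratio: float | None = None


@dataclass
class TreatmentEffect:
    """Treated-vs-control group contrast in the instrument's reporting format."""

    percent_of_control: float
    fold_change: float
    sd_percent: float
    n_treated: int
    n_control: int


def relative_level(
    measurement: QpcrMeasurement,
    efficiency: float = 2.0,
    per_replicate: bool = False,
) -> RelativeLevel:
    """Target level relative to the reference assay.

    By default replicate Cq values are averaged first and the mean
    difference exponentiated (instrument convention); ``per_replicate=True``
    instead averages per-replicate levels.  A target at the no-amplification
    sentinel (max cycles) gives level 0, ``detected=False``; a reference at
    the sentinel raises :class:`ReferenceFailureError`.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    m = measurement
    if np.any(m.reference_cq >= m.max_cycles):
        raise ReferenceFailureError(
            f"sample {m.sample_id!r}: reference {m.reference!r} did not amplify"
        )
    if np.all(m.target_cq >= m.max_cycles):
        return RelativeLevel(m.sample_id, 0.0, detected=False)
    if per_replicate:
        k = min(m.target_cq.size, m.reference_cq.size)
        levels = efficiency ** (m.reference_cq[:k] - m.target_cq[:k])
        return RelativeLevel(m.sample_id, float(np.mean(levels)))
    delta = float(np.mean(m.reference_cq)) - float(np.mean(m.target_cq))
    return RelativeLevel(m.sample_id, float(efficiency**delta))


def calibrated_fold(sample_level: RelativeLevel, calibrator_level: RelativeLevel) -> float:
    """Ratio of a sample's level to a calibrator's (e.g. tumor vs paired normal).

    A calibrator at zero with a detected sample signal means methylation
    over an unmethylated background: returns ``inf`` (treated as a positive
    hypermethylation call downstream).  Zero over zero is NaN (undefined).
    """
    if calibrator_level.level > 0:
        return sample_level.level / calibrator_level.level
    if sample_level.level > 0:
        return math.inf
    return math.nan


def call_hypermethylation_qmsp(fold: float, cutoff: float = 2.0) -> bool:
    """QMSP hypermethylation call: tumor at least ``cutoff``-fold the paired normal.

    Inclusive ("at least twofold"): fold == cutoff is a positive call, and
    an infinite fold (methylated tumor over unmethylated normal) is positive.
    """
    if math.isnan(fold):
        return False
    return fold >= cutoff


def call_low_expression(fold: float, cutoff: float = 0.5) -> bool:
    """Low-expression call: tumor/normal mRNA ratio at or below ``cutoff``.

    Inclusive, mirroring the at-least-twofold hypermethylation rule; an
    undetected target (fold 0) is a positive low-expression call.
    """
    if math.isnan(fold):
        return False
    return fold <= cutoff


def treatment_effect(treated_levels, control_levels) -> TreatmentEffect:
    """Group effect of a treatment, as percent-of-control and fold change.

    percent = 100 * mean(treated) / mean(control); fold is the same ratio
    unscaled.  The treated-group standard deviation is propagated onto the
    percent scale (sd(treated) / mean(control) * 100).
    """
    treated = np.asarray(list(treated_levels), dtype=float)
    control = np.asarray(list(control_levels), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    control_mean = float(np.mean(control))
    if control_mean <= 0:
        raise ValueError("control mean must be positive for a percent-of-control report")
    fold = float(np.mean(treated)) / control_mean
    sd_pct = float(np.std(treated, ddof=1) / control_mean * 100.0) if treated.size > 1 else 0.0
    return TreatmentEffect(
        percent_of_control=100.0 * fold,
        fold_change=fold,
        sd_percent=sd_pct,
        n_treated=int(treated.size),
        n_control=int(control.size),
    )
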