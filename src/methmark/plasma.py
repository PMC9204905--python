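"""Circulating methylated-DNA surveillance.

Classifies longitudinal plasma trajectories of a circulating methylated
marker (normalized to circulating ACTB) into cleared vs returning signal,
issues patient-level progression predictions, and benchmarks the marker
against the serum proteins CEA and CA15-3.

The calling rules: a timepoint is *abnormal* when the plasma ratio strictly
exceeds 0.002; a patient is *high methylation* (progression predicted) when
any timepoint after the post-treatment clearance window is abnormal; serum
CEA is abnormal above 5 ng/mL and CA15-3 above 25 U/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diagnostics import ConfusionTable, DiagnosticReport, RocResult, confusion_metrics, roc_auc

__all__ = [
    "PlasmaSeries",
    "MonitoringCall",
    "PLASMA_CUTOFF",
    "CEA_CUTOFF",
    "CA153_CUTOFF",
    "classify_timepoint",
    "classify_patient",
    "serum_marker_call",
    "benchmark_markers",
]

#: Abnormality cutoff on the methylated-target / ACTB plasma ratio (strict >).
PLASMA_CUTOFF = 0.002
#: Serum CEA abnormality cutoff, ng/mL (strict >).
CEA_CUTOFF = 5.0
#: Serum CA15-3 abnormality cutoff, U/mL (strict >).
CA153_CUTOFF = 25.0


@dataclass
class PlasmaSeries:
    """One patient's ordered plasma timepoints with serum markers and outcome."""

    patient_id: str
    months: np.ndarray          # months from treatment start, strictly increasing
    levels: np.ndarray          # methylated-target/ACTB ratio per timepoint, >= 0
    cea: np.ndarray             # ng/mL (NaN = not measured)
    ca153: np.ndarray           # U/mL (NaN = not measured)
    outcome: str = "non_progression"   # progression | non_progression
    therapy: str = "other"             # hormone_therapy | other

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        self.cea = np.asarray(self.cea, dtype=float)
        self.ca153 = np.asarray(self.ca153, dtype=float)
        if np.any(np.diff(self.months) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.levels[np.isfinite(self.levels)] < 0):
            raise ValueError("plasma levels must be nonnegative")


@dataclass
class MonitoringCall:
    """Per-timepoint statuses and the patient-level progression prediction."""

    patient_id: str
    timepoint_status: list  # "normal" | "abnormal" | None per timepoint
    patient_status: str     # "high_methylation" | "no_methylation" | "indeterminate"
    predicted_outcome: str  # "progression" | "non_progression" | "indeterminate"


def classify_timepoint(level: float, cutoff: float = PLASMA_CUTOFF):
    """Abnormal iff the plasma ratio strictly exceeds the cutoff.

    A level exactly at the cutoff is normal ("higher than" is strict);
    a missing level gives a missing status (None).
    """
    if level is None or (isinstance(level, float) and math.isnan(level)):
        return None
    if level < 0:
        raise ValueError("plasma level must be nonnegative")
    return "abnormal" if level > cutoff else "normal"


def classify_patient(
    series: PlasmaSeries,
    cutoff: float = PLASMA_CUTOFF,
    clearance_window: int = 1,
) -> MonitoringCall:
    """Patient-level call from the trajectory, ignoring the clearance window.

    Baseline circulating signal is expected even in eventual non-progressors
    and takes a few draws to clear, so timepoint indices ``<= clearance_window``
    are not scored.  The patient is *high_methylation* (progression
    predicted) iff any later timepoint is abnormal.  With every timepoint
    inside the window the call is indeterminate.
    """
    statuses = [classify_timepoint(lv, cutoff) for lv in series.levels]
    post = [s for i, s in enumerate(statuses) if i > clearance_window]
    if not post:
        return MonitoringCall(series.patient_id, statuses, "indeterminate", "indeterminate")
    if any(s == "abnormal" for s in post):
        return MonitoringCall(series.patient_id, statuses, "high_methylation", "progression")
    return MonitoringCall(series.patient_id, statuses, "no_methylation", "non_progression")


def serum_marker_call(cea: float, ca153: float):
    """Per-marker abnormality: CEA > 5 ng/mL, CA15-3 > 25 U/mL (both strict).

    Missing values give missing calls (None).  Returns ``(cea_status,
    ca153_status)`` as "normal"/"abnormal"/None.
    """

    def _one(value, cutoff):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if value < 0:
            raise ValueError("marker concentrations must be nonnegative")
        return "abnormal" if value > cutoff else "normal"

    return _one(cea, CEA_CUTOFF), _one(ca153, CA153_CUTOFF)


def _max_post_window(values: np.ndarray, clearance_window: int) -> float:
    post = values[clearance_window + 1 :]
    post = post[np.isfinite(post)]
    return float(post.max()) if post.size else 0.0


def benchmark_markers(
    cohort: list[PlasmaSeries],
    cutoff: float = PLASMA_CUTOFF,
    clearance_window: int = 1,
) -> dict:
    """Cohort-level benchmark of the methylation call against CEA and CA15-3.

    For each marker: a fixed-threshold confusion-table report (methylation by
    the any-abnormal-after-window rule; serum markers by any post-window
    exceedance of their clinical cutoffs) plus a ROC curve using each
    patient's maximum post-window value as the score.

    Returns ``{"methylation": {"report": DiagnosticReport, "roc": RocResult},
    "cea": ..., "ca153": ...}``.
    """
    truth = np.array([s.outcome == "progression" for s in cohort])
    if truth.all() or not truth.any():
        raise ValueError("cohort must contain both outcomes")

    meth_pred = np.array(
        [classify_patient(s, cutoff, clearance_window).predicted_outcome == "progression"
         for s in cohort]
    )
    meth_scores = np.array([_max_post_window(s.levels, clearance_window) for s in cohort])
    cea_scores = np.array([_max_post_window(s.cea, clearance_window) for s in cohort])
    ca_scores = np.array([_max_post_window(s.ca153, clearance_window) for s in cohort])

    out = {}
    for name, pred, scores in (
        ("methylation", meth_pred, meth_scores),
        ("cea", cea_scores > CEA_CUTOFF, cea_scores),
        ("ca153", ca_scores > CA153_CUTOFF, ca_scores),
    ):
        report = confusion_metrics(ConfusionTable.from_calls(pred, truth))
        roc = roc_auc(scores, truth.astype(int))
        out[name] = {"report": report, "roc": roc}
    return out
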