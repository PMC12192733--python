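"""Single-point fluorogenic enzyme-inhibition assay analysis.

Enzymatic activity is the slope of the fluorescence trace between
minutes 10 and 20; percent inhibition compares a sample slope to the
uninhibited control. Hits are compounds with inhibition strictly above
the cutoff (15% by default, the usual single-point triage level at low
test concentrations). ``score_screen`` then compares model predictions
against experimental hit calls as a confusion matrix with
screening-style summary rates (PPV, NPV, TPR, TNR, ACC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import ConfusionCounts, classification_metrics

HIT_CUTOFF_PERCENT = 15.0
SLOPE_WINDOW = (10.0, 20.0)  # minutes


@dataclass
class KineticTrace:
    """One fluorescence time course (times in minutes, signal in FLU)."""

    compound_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    role: str = "sample"  # "control" | "sample"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must be aligned 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.role not in ("control", "sample"):
            raise ValueError("role must be 'control' or 'sample'")


@dataclass
class HitCall:
    compound_id: str
    percent_inhibition: float
    active: bool
    cutoff: float = HIT_CUTOFF_PERCENT
    concentration_um: float = 1.5


def slope(trace: KineticTrace) -> float:
    """Fluorescence slope between minutes 10 and 20, in FLU/minute.

    Readings exactly at the window edges are used directly; otherwise
    they are linearly interpolated from bracketing timepoints.
    """
    t0, t1 = SLOPE_WINDOW
    if trace.times[0] > t0 or trace.times[-1] < t1:
        raise ValueError(
            f"trace does not cover the {t0:g}-{t1:g} minute window"
        )
    f0 = float(np.interp(t0, trace.times, trace.fluorescence))
    f1 = float(np.interp(t1, trace.times, trace.fluorescence))
    return (f1 - f0) / (t1 - t0)


def percent_inhibition(slope_control: float, slope_sample: float) -> float:
    """100 * (slope_control - slope_sample) / slope_control.

    Negative values (activation) are reported as-is.
    """
    if not (slope_control > 0):
        raise ValueError("invalid control: control slope must be positive")
    return 100.0 * (slope_control - slope_sample) / slope_control


def call_hits(
    inhibitions: Mapping[str, float],
    cutoff: float = HIT_CUTOFF_PERCENT,
    concentration_um: float = 1.5,
) -> list[HitCall]:
    """Call hits at strict > cutoff; exactly-at-cutoff is inactive."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return [
        HitCall(
            compound_id=cid,
            percent_inhibition=float(v),
            active=float(v) > cutoff,
            cutoff=cutoff,
            concentration_um=concentration_um,
        )
        for cid, v in inhibitions.items()
    ]


def analyze_kinetics(
    table: pd.DataFrame,
    cutoff: float = HIT_CUTOFF_PERCENT,
) -> list[HitCall]:
    """Full assay analysis from a long kinetics table with columns
    (compound_id, role, time_min, flu).

    Replicate traces per compound are analyzed separately and their
    slopes averaged. Control slopes (role == "control") are pooled into
    one mean control slope.
    """
    required = {"compound_id", "role", "time_min", "flu"}
    if not required.issubset(table.columns):
        raise ValueError(f"kinetics table needs columns {sorted(required)}")

    slopes: dict[str, list[float]] = {}
    control_slopes: list[float] = []
    group_cols = ["compound_id", "role"]
    if "replicate" in table.columns:
        group_cols.append("replicate")
    for keys, grp in table.groupby(group_cols, sort=False):
        cid, role = keys[0], keys[1]
        grp = grp.sort_values("time_min")
        trace = KineticTrace(
            compound_id=str(cid),
            times=grp["time_min"].to_numpy(),
            fluorescence=grp["flu"].to_numpy(),
            role=role,
        )
        s = slope(trace)
        if role == "control":
            control_slopes.append(s)
        else:
            slopes.setdefault(str(cid), []).append(s)
    if not control_slopes:
        raise ValueError("no control trace found")
    control = float(np.mean(control_slopes))
    inhibitions = {
        cid: percent_inhibition(control, float(np.mean(vals)))
        for cid, vals in slopes.items()
    }
    return call_hits(inhibitions, cutoff=cutoff)


def score_screen(
    predicted_labels: Mapping[str, bool],
    hit_calls: Sequence[HitCall],
) -> tuple[ConfusionCounts, dict[str, float | None]]:
    """Confusion matrix of predictions vs experimental hit calls.

    Experimental calls are the ground truth. Returns the counts and a
    screening-style report: PPV, NPV, TPR, TNR and ACC (plus F1 and
    MCC from the underlying metrics).
    """
    experimental = {h.compound_id: h.active for h in hit_calls}
    missing_pred = sorted(set(experimental) - set(predicted_labels))
    missing_exp = sorted(set(predicted_labels) - set(experimental))
    if missing_pred or missing_exp:
        raise ValueError(
            f"unmatched ids: missing predictions for {missing_pred}, "
            f"missing hit calls for {missing_exp}"
        )
    tp = tn = fp = fn = 0
    for cid, truth in experimental.items():
        pred = bool(predicted_labels[cid])
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    m = classification_metrics(counts)
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    report = {
        "PPV": m.precision,
        "NPV": npv,
        "TPR": m.recall,
        "TNR": m.specificity,
        "ACC": m.accuracy,
        "F1": m.f1,
        "MCC": m.mcc,
    }
    return counts, report


def screen_summary_text(counts: ConfusionCounts, report: Mapping[str, float | None]) -> str:
    """Human-readable confusion summary for a prediction-vs-assay screen."""
    lines = [
        "Prediction vs experiment (experimental hit calls are truth)",
        f"  TP={counts.tp}  FP={counts.fp}",
        f"  FN={counts.fn}  TN={counts.tn}",
    ]
    for key in ("PPV", "NPV", "TPR", "TNR", "ACC"):
        v = report.get(key)
        lines.append(f"  {key}: {'undefined' if v is None else f'{100 * v:.0f}%'}")
    return "\n".join(lines)
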