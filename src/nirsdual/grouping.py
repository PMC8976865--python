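"""Slope-sign grouping of subjects by scan-performance trend.

Per subject, the median scan fraction over subareas is taken for each easy
session, an ordinary least-squares line is fit through the three medians
(sessions coded 1..3), and the sign of the slope assigns the subject to the
Attention-focused group (positive slope: scanning improved with practice) or
the Accuracy-focused group (negative slope). An exactly zero slope -- a
measure-zero event with continuous scores -- falls to the Accuracy-focused
side and is flagged, since a strictly positive slope is the membership test
for the Attention-focused group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EASY_SESSIONS = ("E1", "E2", "E3")

ATTENTION = "attention"
ACCURACY = "accuracy"


@dataclass(frozen=True)
class GroupAssignment:
    subject: str
    medians: tuple[float, ...]
    slope: float
    intercept: float
    group: str
    tie_flag: bool


def session_medians(
    scores: pd.DataFrame, subject: str, sessions: tuple[str, ...] = EASY_SESSIONS,
    measure: str = "scan",
) -> np.ndarray:
    """Per-easy-session median of the measure over that subject's subareas."""
    sub = scores[scores["subject"] == subject]
    out = []
    for s in sessions:
        vals = sub.loc[sub["session"] == s, measure].dropna()
        if len(vals) == 0:
            raise ValueError(f"subject {subject}: no {measure} scores in session {s}")
        out.append(float(vals.median()))
    return np.array(out)


def fit_slope(medians: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS through (1, m1), (2, m2), (3, m3)."""
    y = np.asarray(medians, dtype=float)
    if len(y) != 3:
        raise ValueError("expected exactly 3 easy-session medians")
    x = np.arange(1, 4, dtype=float)
    xc = x - x.mean()
    slope = float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def assign_group(slope: float) -> tuple[str, bool]:
    """(group, tie_flag): positive slope -> attention, otherwise accuracy."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if slope > 0:
        return ATTENTION, False
    return ACCURACY, slope == 0


def assign_groups(scores: pd.DataFrame, measure: str = "scan") -> pd.DataFrame:
    """GroupAssignment table for every subject in the score table."""
    rows = []
    for subject in sorted(scores["subject"].unique()):
        med = session_medians(scores, subject, measure=measure)
        slope, intercept = fit_slope(med)
        group, tie = assign_group(slope)
        rows.append({
            "subject": subject,
            "median_E1": med[0], "median_E2": med[1], "median_E3": med[2],
            "slope": slope, "intercept": intercept,
            "group": group, "tie_flag": tie,
        })
    return pd.DataFrame(rows)
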