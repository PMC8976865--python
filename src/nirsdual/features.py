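"""Trimmed-window fNIRS features and relative efficiency / involvement.

Per subarea and channel, HbO/HbR are averaged between 15 s after subarea
onset and 15 s before its end (a 90-s window for a 2-min subarea), washing
out hemodynamic carry-over from the preceding subarea. Performance (P) and
mental effort (M) are z-standardized over the full observation pool, HbR is
sign-flipped before standardization (more-negative HbR = more effort), and
the 45-degree rotation

    RE = (P - M) / sqrt(2),    RI = (P + M) / sqrt(2)

maps each observation into efficiency/involvement coordinates: positive RE
means performance above the effort expended, positive RI means engagement of
both performance and effort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import HemoTimeSeries

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class FeatureConfig:
    trim_s: float = 15.0
    # channels most affected by the dual task; their HbO/HbR pair with
    # behavioral P in the efficiency analysis
    focus_channels: tuple[int, ...] = (2, 7, 12)
    short_channels: tuple[int, ...] = (17, 18)
    standardize_within: tuple[str, ...] = ()   # e.g. ("session",) for per-session pools


def epoch_mean(
    t: np.ndarray,
    series: np.ndarray,
    t_start: float,
    t_end: float,
    trim_s: float = 15.0,
) -> float:
    """Arithmetic mean over [t_start + trim, t_end - trim); NaN if empty."""
    if t_end - t_start <= 2 * trim_s:
        logger.warning("subarea [%s, %s) too short for %.0f-s trims; missing value",
                       t_start, t_end, trim_s)
        return float("nan")
    sel = (t >= t_start + trim_s) & (t < t_end - trim_s)
    if not sel.any():
        logger.warning("empty epoch window; missing value")
        return float("nan")
    return float(np.mean(series[sel]))


def subarea_features(hemo: HemoTimeSeries, cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-channel trimmed means per subarea, plus the short-channel average
    (the extracerebral covariate) repeated on each row."""
    cfg = cfg or FeatureConfig()
    rows = []
    n_ch = hemo.hbo.shape[0]
    for k, onset in enumerate(hemo.subarea_onsets, start=1):
        t0, t1 = onset, onset + hemo.subarea_duration
        means_hbo = np.array([
            epoch_mean(hemo.t, hemo.hbo[j], t0, t1, cfg.trim_s) for j in range(n_ch)])
        means_hbr = np.array([
            epoch_mean(hemo.t, hemo.hbr[j], t0, t1, cfg.trim_s) for j in range(n_ch)])
        short_idx = [c - 1 for c in cfg.short_channels]
        with np.errstate(invalid="ignore"):
            short_hbo = np.nanmean(means_hbo[short_idx])
            short_hbr = np.nanmean(means_hbr[short_idx])
        for j in range(n_ch):
            if j in short_idx:
                continue
            rows.append({
                "subject": hemo.subject, "session": hemo.session, "subarea": k,
                "channel": j + 1,
                "mean_hbo": means_hbo[j], "mean_hbr": means_hbr[j],
                "short_mean_hbo": short_hbo, "short_mean_hbr": short_hbr,
            })
    return pd.DataFrame(rows)


def standardize(values: pd.Series | np.ndarray, ddof: int = 1) -> np.ndarray:
    """z = (x - mean) / SD with the sample (n-1) SD; NaNs pass through."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = np.std(x[finite], ddof=ddof)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot standardize")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - np.mean(x[finite])) / sd
    return out


def relative_efficiency_involvement(
    p: np.ndarray | float, m: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """RE = (P - M)/sqrt(2); RI = (P + M)/sqrt(2)."""
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    return (p - m) / SQRT2, (p + m) / SQRT2


def efficiency_table(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: FeatureConfig | None = None,
    performance_measures: tuple[str, ...] = ("scan", "adp_tf"),
) -> pd.DataFrame:
    """EfficiencyPoint rows: one per (observation, focus channel, biomarker,
    performance measure).

    P is the standardized behavioral measure; M is the standardized channel
    mean (HbR sign-flipped first). Standardization pools all observations
    per measure (optionally within groups of columns via
    ``cfg.standardize_within``); missing epochs stay missing.
    """
    cfg = cfg or FeatureConfig()
    feats = features[features["channel"].isin(cfg.focus_channels)].copy()
    merged = feats.merge(scores, on=["subject", "session", "subarea"], how="inner")

    def zcol(df: pd.DataFrame, col: str, flip: bool = False) -> np.ndarray:
        vals = -df[col] if flip else df[col]
        if cfg.standardize_within:
            return (vals.groupby([df[c] for c in cfg.standardize_within])
                        .transform(lambda s: standardize(s)))
        return standardize(vals)

    out = []
    for pm in performance_measures:
        base = merged.copy()
        base["P"] = zcol(base, pm)
        for biomarker, col, flip in (("hbo", "mean_hbo", False), ("hbr", "mean_hbr", True)):
            # effort must be standardized per channel: channels differ in scale
            m = np.full(len(base), np.nan)
            for ch in cfg.focus_channels:
                sel = (base["channel"] == ch).to_numpy()
                vals = base.loc[sel, col]
                m[sel] = standardize(-vals if flip else vals)
            re, ri = relative_efficiency_involvement(base["P"].to_numpy(), m)
            out.append(pd.DataFrame({
                "subject": base["subject"], "session": base["session"],
                "subarea": base["subarea"], "channel": base["channel"],
                "performance_measure": pm, "biomarker": biomarker,
                "P": base["P"].to_numpy(), "M": m, "RE": re, "RI": ri,
            }))
    return pd.concat(out, ignore_index=True)
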