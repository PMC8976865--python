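"""Behavioral dependent variables from simulator-style logs.

Per subarea: the fraction of the assigned region covered (scan), missed
(not scan), and coverage spilled outside it (over scan); a zoom-gated
target-find accuracy; and the adaptive target-find score (accuracy divided
by the 1-based subarea number, discounting later subareas whose outcome can
ride on earlier ones).

Coverage ratios are normalized by the union of coverage and ROI by default
(|C n ROI|, |ROI \\ C|, |C \\ ROI| over |C u ROI|), the convention under
which the three ratios sum to one; an |ROI|-denominator alternative is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .sim.behavior import BehaviorLog, FovSnapshot

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    bottom_max_size: float = 750.0
    fov_area_ratio: float = 0.50
    zoom_max_deg: float = 15.0
    dwell_s: float = 3.0
    denominator: str = "union"   # or "roi"


@dataclass(frozen=True)
class SubareaScore:
    subject: str
    session: str
    subarea: int
    scan: float
    not_scan: float
    over_scan: float
    accuracy: int
    adp_tf: float

    def __post_init__(self) -> None:
        for name in ("scan", "not_scan", "over_scan", "adp_tf"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.accuracy not in (0, 1):
            raise ValueError("accuracy must be 0 or 1")


def filter_fov_polygons(
    polys: list[FovSnapshot], cfg: ScoringConfig | None = None
) -> list[FovSnapshot]:
    """Keep FOV footprints with bottom_max_size < 750 and area ratio < 0.50.

    Oversized footprints occur when the camera grazes the horizon and the
    projected quadrilateral degenerates; they would swamp the coverage union.
    """
    cfg = cfg or ScoringConfig()
    out = []
    for p in polys:
        if p.bottom_max_size is None or p.fov_area_ratio is None:
            logger.warning("FOV polygon missing attributes; excluded")
            continue
        if p.bottom_max_size < cfg.bottom_max_size and p.fov_area_ratio < cfg.fov_area_ratio:
            out.append(p)
    return out


def _valid(geom: Polygon) -> Polygon:
    if not geom.is_valid:
        geom = geom.buffer(0)
        if not geom.is_valid:
            raise ValueError("invalid geometry could not be repaired")
    return geom


def coverage_ratios(
    roi: Polygon,
    retained: list[FovSnapshot] | list[Polygon],
    denominator: str = "union",
) -> tuple[float, float, float]:
    """(scan, not_scan, over_scan) for one subarea."""
    roi = _valid(roi)
    if roi.area <= 0:
        raise ValueError("degenerate ROI")
    geoms = [p.polygon if isinstance(p, FovSnapshot) else p for p in retained]
    covered = _valid(unary_union([_valid(g) for g in geoms])) if geoms else Polygon()
    inside = covered.intersection(roi).area
    outside = covered.difference(roi).area
    missed = roi.area - inside
    denom = roi.area + outside if denominator == "union" else roi.area
    return inside / denom, missed / denom, outside / denom


def target_accuracy(
    t: np.ndarray,
    zoom_deg: np.ndarray,
    target_in_fov: np.ndarray,
    target_present: bool = True,
    dwell_s: float = 3.0,
    zoom_max_deg: float = 15.0,
) -> int:
    """1 iff some contiguous run with the target in FOV at zoom <= the gate
    spans at least ``dwell_s`` seconds (timestamp span, so the result is
    invariant to resampling). Subareas without a target score 1."""
    if not target_present:
        return 1
    t = np.asarray(t, dtype=float)
    if len(t) == 0:
        raise ValueError("empty series for a subarea with a target")
    ok = (np.asarray(target_in_fov) == 1) & (np.asarray(zoom_deg) <= zoom_max_deg)
    if not ok.any():
        return 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    for i0, i1 in zip(starts, stops):
        if t[i1 - 1] - t[i0] >= dwell_s:
            return 1
    return 0


def adaptive_target_find(accuracy: int, subarea_index: int) -> float:
    """Accuracy discounted by the 1-based subarea number."""
    if subarea_index < 1:
        raise ValueError("subarea index is 1-based")
    return accuracy / subarea_index


def score_log(log: BehaviorLog, cfg: ScoringConfig | None = None) -> SubareaScore:
    cfg = cfg or ScoringConfig()
    retained = filter_fov_polygons(log.fov, cfg)
    scan, not_scan, over = coverage_ratios(log.roi, retained, cfg.denominator)
    acc = target_accuracy(log.t, log.zoom_deg, log.target_in_fov,
                          log.target_present, cfg.dwell_s, cfg.zoom_max_deg)
    return SubareaScore(
        subject=log.subject, session=log.session, subarea=log.subarea_index,
        scan=scan, not_scan=not_scan, over_scan=over, accuracy=acc,
        adp_tf=adaptive_target_find(acc, log.subarea_index),
    )


def score_logs(logs: list[BehaviorLog], cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Tidy score table keyed by (subject, session, subarea)."""
    rows = [score_log(lg, cfg).__dict__ for lg in logs]
    return pd.DataFrame(rows)
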