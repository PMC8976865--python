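"""Behavioral log generator for the scan + target-find dual task.

Geometry mode emits an assigned-ROI rectangle and timestamped camera
field-of-view (FOV) polygons whose union coverage realizes a planted scan
fraction (group mean + slope x easy-session index + noise), plus zoom and
target-in-FOV traces consistent with a planted accuracy trend. Invalid FOV
polygons (oversized footprints near the horizon) are injected so that the
scoring module's polygon filter is genuinely exercised.

Ratios mode skips geometry and emits subarea score rows directly; it exists
for statistics-level simulation experiments where only the planted score
structure matters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .config import EASY_SESSIONS, ScenarioConfig

logger = logging.getLogger(__name__)

ROI_SIZE = 1000.0   # m, side of the assigned square region
GRID = 20           # coverage grid resolution per side


@dataclass
class FovSnapshot:
    t: float
    polygon: Polygon
    bottom_max_size: float
    fov_area_ratio: float


@dataclass
class BehaviorLog:
    """One subject x session x subarea of simulator-style output."""

    subject: str
    session: str
    subarea_index: int          # 1-based
    roi: Polygon
    fov: list[FovSnapshot]
    t: np.ndarray               # s, within-subarea clock
    zoom_deg: np.ndarray
    target_present: bool
    target_in_fov: np.ndarray   # 0/1
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.subarea_index:
            raise ValueError("subarea index is 1-based")
        if len(self.zoom_deg) != len(self.t) or len(self.target_in_fov) != len(self.t):
            raise ValueError("zoom/indicator series must align with t")
        if np.any(self.zoom_deg <= 0):
            raise ValueError("zoom must be positive")


def _easy_index(session: str) -> int:
    """0,1,2 across E1..E3; hard sessions hold the E3 level."""
    if session in EASY_SESSIONS:
        return EASY_SESSIONS.index(session)
    return len(EASY_SESSIONS) - 1


def _planted_scan(cfg: ScenarioConfig, group: str, subj_offset: float,
                  session: str, rng: np.random.Generator) -> float:
    base = cfg.scan_base_by_group.get(group, 0.5)
    slope = cfg.scan_slope_by_group.get(group, 0.0)
    s = base + subj_offset + slope * _easy_index(session) \
        + cfg.scan_noise_sd * rng.standard_normal()
    if not 0.0 <= s <= 1.0:
        logger.warning("planted scan fraction %.3f outside [0,1]; clipped", s)
        s = float(np.clip(s, 0.0, 1.0))
    return s


def _coverage_polygons(
    rng: np.random.Generator, scan: float, over: float, t: np.ndarray
) -> list[FovSnapshot]:
    """FOV rectangles realizing |C inter ROI|/|C union ROI| = scan and
    |C minus ROI|/|C union ROI| = over, via disjoint grid cells."""
    a = scan / (1.0 - over)          # covered fraction of the ROI
    b = over / (1.0 - over)         # outside area as fraction of |ROI|
    a = min(a, 1.0)
    cell = ROI_SIZE / GRID
    n_in = int(round(a * GRID * GRID))
    n_out = int(round(b * GRID * GRID))

    cells_in = [(i, j) for i in range(GRID) for j in range(GRID)]
    idx = rng.permutation(len(cells_in))[:n_in]
    # outside cells: strip to the right of the ROI
    cells_out = [(GRID + i, j) for i in range(GRID) for j in range(GRID)]
    idx_out = rng.permutation(len(cells_out))[:n_out]

    chosen = [cells_in[k] for k in idx] + [cells_out[k] for k in idx_out]
    rng.shuffle(chosen)
    out: list[FovSnapshot] = []
    times = np.sort(rng.uniform(t[0], t[-1], size=len(chosen)))
    for (i, j), tt in zip(chosen, times):
        poly = box(i * cell, j * cell, (i + 1) * cell, (j + 1) * cell)
        out.append(FovSnapshot(
            t=float(tt), polygon=poly,
            bottom_max_size=float(rng.uniform(200, 700)),
            fov_area_ratio=float(rng.uniform(0.05, 0.45)),
        ))
    # oversized near-horizon footprints the scorer must discard
    for _ in range(rng.integers(1, 4)):
        cx = rng.uniform(0, ROI_SIZE)
        big = box(cx - 2 * ROI_SIZE, -2 * ROI_SIZE, cx + 2 * ROI_SIZE, 2 * ROI_SIZE)
        bad_bottom = rng.random() < 0.5
        out.append(FovSnapshot(
            t=float(rng.uniform(t[0], t[-1])), polygon=big,
            bottom_max_size=float(rng.uniform(800, 2000)) if bad_bottom
            else float(rng.uniform(200, 700)),
            fov_area_ratio=float(rng.uniform(0.55, 0.95)) if not bad_bottom
            else float(rng.uniform(0.05, 0.45)),
        ))
    out.sort(key=lambda s: s.t)
    return out


def _zoom_and_target(
    rng: np.random.Generator, t: np.ndarray, fs: float,
    target_present: bool, accurate: bool,
    zoom_max_deg: float = 15.0, dwell_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Zoom trace and 0/1 indicator realizing the planted accuracy outcome.

    An accurate find is a contiguous >= dwell run with the target in FOV at
    zoom <= zoom_max_deg; an inaccurate one includes only sub-dwell or
    high-zoom glimpses.
    """
    n = len(t)
    zoom = rng.uniform(18.0, 40.0, size=n)  # wandering above the gate
    tif = np.zeros(n, dtype=int)
    if not target_present:
        return zoom, tif

    def carve(start_s: float, dur_s: float, zoom_val: float, in_fov: bool) -> None:
        i0 = int(round(start_s * fs))
        i1 = min(n, i0 + int(round(dur_s * fs)))
        zoom[i0:i1] = zoom_val
        if in_fov:
            tif[i0:i1] = 1

    # brief high-zoom glimpses of the target (never satisfy the gate)
    for _ in range(rng.integers(0, 3)):
        carve(rng.uniform(5, t[-1] - 10), rng.uniform(0.5, 2.0),
              rng.uniform(zoom_max_deg + 5, 35), in_fov=True)
    if accurate:
        dur = rng.uniform(dwell_s + 1.0, dwell_s + 5.0)
        carve(rng.uniform(10, t[-1] - dur - 5), dur,
              rng.uniform(3.0, zoom_max_deg - 3.0), in_fov=True)
    else:
        # low-zoom look that breaks off before the dwell requirement
        carve(rng.uniform(10, t[-1] - 10), max(0.5, dwell_s - 1.0),
              rng.uniform(3.0, zoom_max_deg - 3.0), in_fov=True)
    return zoom, tif


def simulate_behavior(cfg: ScenarioConfig) -> list[BehaviorLog]:
    """Geometry-mode logs for every subject x session x subarea."""
    logs: list[BehaviorLog] = []
    groups = cfg.groups()
    roi = box(0.0, 0.0, ROI_SIZE, ROI_SIZE)
    n = int(round(cfg.subarea_duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    for subject in cfg.subjects:
        group = groups[subject]
        rng_subj = cfg.rng(subject, "behavior")
        subj_offset = cfg.subject_sd * rng_subj.standard_normal()
        for session in cfg.sessions:
            for k in range(1, cfg.subareas_per_session + 1):
                rng = cfg.rng(subject, session, "behavior", k)
                scan = _planted_scan(cfg, group, subj_offset, session, rng)
                over = float(np.clip(
                    cfg.over_scan_mean + cfg.over_scan_sd * rng.standard_normal(),
                    0.02, 0.45))
                scan = min(scan, 1.0 - over - 1e-3)
                fov = _coverage_polygons(rng, scan, over, t)

                target_present = bool(rng.random() < cfg.target_rate)
                p_acc = float(np.clip(
                    cfg.accuracy_base_by_group.get(group, 0.5)
                    + cfg.accuracy_slope_by_group.get(group, 0.0) * _easy_index(session),
                    0.0, 1.0))
                accurate = bool(rng.random() < p_acc) if target_present else True
                zoom, tif = _zoom_and_target(rng, t, cfg.fs, target_present, accurate)
                logs.append(BehaviorLog(
                    subject=subject, session=session, subarea_index=k,
                    roi=roi, fov=fov, t=t, zoom_deg=zoom,
                    target_present=target_present, target_in_fov=tif,
                    planted={"group": group, "scan": scan, "over_scan": over,
                             "accuracy": int(accurate)},
                ))
    return logs


def simulate_scores(cfg: ScenarioConfig) -> pd.DataFrame:
    """Ratios-only fast mode: subarea score rows with the planted structure,
    bypassing geometry and the scoring module."""
    rows = []
    groups = cfg.groups()
    for subject in cfg.subjects:
        group = groups[subject]
        rng_subj = cfg.rng(subject, "behavior")
        subj_offset = cfg.subject_sd * rng_subj.standard_normal()
        for session in cfg.sessions:
            for k in range(1, cfg.subareas_per_session + 1):
                rng = cfg.rng(subject, session, "behavior", k)
                scan = _planted_scan(cfg, group, subj_offset, session, rng)
                over = float(np.clip(
                    cfg.over_scan_mean + cfg.over_scan_sd * rng.standard_normal(),
                    0.02, 0.45))
                scan = min(scan, 1.0 - over - 1e-3)
                target_present = bool(rng.random() < cfg.target_rate)
                p_acc = float(np.clip(
                    cfg.accuracy_base_by_group.get(group, 0.5)
                    + cfg.accuracy_slope_by_group.get(group, 0.0) * _easy_index(session),
                    0.0, 1.0))
                acc = int(rng.random() < p_acc) if target_present else 1
                rows.append({
                    "subject": subject, "group": group, "session": session,
                    "subarea": k, "scan": scan, "not_scan": 1.0 - scan - over,
                    "over_scan": over, "accuracy": acc, "adp_tf": acc / k,
                    "target_present": target_present,
                })
    return pd.DataFrame(rows)
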