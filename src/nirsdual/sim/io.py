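"""Text exports for synthetic recordings and behavioral logs.

Recordings go to long-format CSV (time, channel, wavelength, intensity) or
SNIRF; behavioral logs to CSV with FOV/ROI geometry as WKT.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ..recording import RawRecording
from .behavior import BehaviorLog


def write_recording_csv(rec: RawRecording, path: str | Path) -> None:
    rec.to_frame().to_csv(path, index=False)


def write_behavior_csv(
    logs: list[BehaviorLog], series_path: str | Path,
    fov_path: str | Path, roi_path: str | Path,
) -> None:
    """Three tables: time series (zoom/indicator), FOV polygons, ROI geometry."""
    series_rows, fov_rows, roi_rows = [], [], {}
    for lg in logs:
        key = (lg.subject, lg.session, lg.subarea_index)
        series_rows.append(pd.DataFrame({
            "subject": lg.subject, "session": lg.session, "subarea": lg.subarea_index,
            "t": lg.t, "zoom_deg": lg.zoom_deg, "target_in_fov": lg.target_in_fov,
            "target_present": int(lg.target_present),
        }))
        for snap in lg.fov:
            fov_rows.append({
                "subject": lg.subject, "session": lg.session,
                "subarea": lg.subarea_index, "t": snap.t,
                "bottom_max_size": snap.bottom_max_size,
                "fov_area_ratio": snap.fov_area_ratio,
                "polygon_wkt": snap.polygon.wkt,
            })
        roi_rows[key] = {"subject": lg.subject, "session": lg.session,
                         "subarea": lg.subarea_index, "roi_wkt": lg.roi.wkt}
    pd.concat(series_rows, ignore_index=True).to_csv(series_path, index=False)
    pd.DataFrame(fov_rows).to_csv(fov_path, index=False)
    pd.DataFrame(list(roi_rows.values())).to_csv(roi_path, index=False)


def read_behavior_csv(
    series_path: str | Path, fov_path: str | Path, roi_path: str | Path,
) -> list[BehaviorLog]:
    from shapely import wkt
    import numpy as np
    from .behavior import FovSnapshot

    series = pd.read_csv(series_path)
    fov = pd.read_csv(fov_path)
    roi = pd.read_csv(roi_path)
    logs = []
    keys = ["subject", "session", "subarea"]
    roi_map = {tuple(r[k] for k in keys): wkt.loads(r["roi_wkt"])
               for _, r in roi.iterrows()}
    fov_groups = dict(tuple(fov.groupby(keys))) if len(fov) else {}
    for key, grp in series.groupby(keys):
        snaps = []
        if key in fov_groups:
            for _, r in fov_groups[key].sort_values("t").iterrows():
                snaps.append(FovSnapshot(
                    t=float(r["t"]), polygon=wkt.loads(r["polygon_wkt"]),
                    bottom_max_size=float(r["bottom_max_size"]),
                    fov_area_ratio=float(r["fov_area_ratio"])))
        grp = grp.sort_values("t")
        logs.append(BehaviorLog(
            subject=key[0], session=key[1], subarea_index=int(key[2]),
            roi=roi_map[key], fov=snaps,
            t=grp["t"].to_numpy(dtype=float),
            zoom_deg=grp["zoom_deg"].to_numpy(dtype=float),
            target_present=bool(grp["target_present"].iloc[0]),
            target_in_fov=grp["target_in_fov"].to_numpy(dtype=int),
        ))
    return logs
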