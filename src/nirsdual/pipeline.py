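"""End-to-end orchestration: simulate -> preprocess -> score -> features ->
group -> model, with tidy-CSV contracts between stages and a reproducibility
manifest (seed, config hash, per-stage row counts, output file hashes).

Behavioral stages communicate through CSV files so any stage can be re-run
from cached upstream outputs. The fNIRS branch (simulate raw -> preprocess ->
subarea features) streams session by session in memory by default -- full raw
time series are bulky -- and persists recordings only when asked; the
feature table it produces is persisted like every other contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureConfig, efficiency_table, subarea_features
from .grouping import assign_groups
from .models import DVAnalysis, analyze_dv
from .preprocess import PreprocessConfig, preprocess
from .scoring import ScoringConfig, score_logs
from .sim import ScenarioConfig, simulate_behavior, simulate_recording
from .sim.io import read_behavior_csv, write_behavior_csv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    run_fnirs: bool = True
    run_behavior: bool = True
    run_models: bool = True
    run_posthoc: bool = True
    persist_recordings: bool = False
    behavior_dvs: tuple[str, ...] = ("scan", "not_scan", "over_scan", "AdpTF")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen_kwargs = raw.get("scenario", {})
        if seed is not None:
            scen_kwargs["seed"] = seed
        cfg = cls(
            scenario=ScenarioConfig(**scen_kwargs),
            scoring=ScoringConfig(**raw.get("scoring", {})),
            features=FeatureConfig(**raw.get("features", {})),
        )
        for key in ("run_fnirs", "run_behavior", "run_models", "run_posthoc",
                    "persist_recordings"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    sim_dir = out / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    logs = simulate_behavior(cfg.scenario)
    write_behavior_csv(logs, sim_dir / "behavior_series.csv",
                       sim_dir / "behavior_fov.csv", sim_dir / "behavior_roi.csv")
    counts = {"behavior_logs": len(logs)}
    if cfg.persist_recordings:
        from .snirf_io import write_snirf
        rec_dir = sim_dir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        n = 0
        for subj in cfg.scenario.subjects:
            for sess in cfg.scenario.sessions:
                rec, _ = simulate_recording(cfg.scenario, subj, sess)
                write_snirf(rec, str(rec_dir / f"{subj}_{sess}.snirf"))
                n += 1
        counts["recordings"] = n
    return counts


def stage_score(cfg: PipelineConfig, out: Path) -> dict:
    sim_dir = out / "sim"
    logs = read_behavior_csv(sim_dir / "behavior_series.csv",
                             sim_dir / "behavior_fov.csv",
                             sim_dir / "behavior_roi.csv")
    scores = score_logs(logs, cfg.scoring)
    scores.to_csv(out / "scores.csv", index=False)
    return {"scores": len(scores)}


def stage_fnirs_features(cfg: PipelineConfig, out: Path) -> dict:
    """Simulate raw recordings, preprocess, extract trimmed-window features."""
    frames = []
    for subj in cfg.scenario.subjects:
        for sess in cfg.scenario.sessions:
            rec, _ = simulate_recording(cfg.scenario, subj, sess)
            hemo = preprocess(rec, cfg.preprocess)
            frames.append(subarea_features(hemo, cfg.features))
    feats = pd.concat(frames, ignore_index=True)
    feats.to_csv(out / "fnirs_features.csv", index=False)
    return {"fnirs_features": len(feats)}


def stage_efficiency(cfg: PipelineConfig, out: Path) -> dict:
    """Relative efficiency/involvement points from features + scores."""
    feats = pd.read_csv(out / "fnirs_features.csv")
    scores = pd.read_csv(out / "scores.csv")
    eff = efficiency_table(feats, scores, cfg.features)
    eff.to_csv(out / "efficiency.csv", index=False)
    return {"efficiency_points": len(eff)}


def stage_group(cfg: PipelineConfig, out: Path) -> dict:
    scores = pd.read_csv(out / "scores.csv")
    groups = assign_groups(scores)
    groups.to_csv(out / "groups.csv", index=False)
    return {"groups": len(groups)}


def _model_frame(scores: pd.DataFrame, groups: pd.DataFrame,
                 feats: pd.DataFrame | None, focus: tuple[int, ...]) -> pd.DataFrame:
    df = scores.merge(groups[["subject", "group"]], on="subject")
    df = df.rename(columns={"subject": "ID", "group": "Group", "session": "Session",
                            "adp_tf": "AdpTF"})
    if feats is not None:
        wide = feats[feats["channel"].isin(focus)].pivot_table(
            index=["subject", "session", "subarea"],
            columns="channel", values=["mean_hbo", "mean_hbr"])
        wide.columns = [f"{m}_ch{c}" for m, c in wide.columns]
        short = feats.groupby(["subject", "session", "subarea"])[
            ["short_mean_hbo", "short_mean_hbr"]].first()
        wide = wide.join(short).reset_index().rename(
            columns={"subject": "ID", "session": "Session"})
        df = df.merge(wide, on=["ID", "Session", "subarea"], how="left")
        df["Short"] = df["short_mean_hbo"]
    return df


def stage_model(cfg: PipelineConfig, out: Path) -> dict:
    scores = pd.read_csv(out / "scores.csv")
    groups = pd.read_csv(out / "groups.csv")
    feats_path = out / "fnirs_features.csv"
    feats = pd.read_csv(feats_path) if feats_path.exists() else None
    df = _model_frame(scores, groups, feats, cfg.features.focus_channels)

    analyses: list[DVAnalysis] = []

    def try_analyze(frame, dv, **kwargs):
        try:
            analyses.append(analyze_dv(frame, dv, **kwargs))
        except RuntimeError as exc:
            logger.warning("skipping DV %s: %s", dv, exc)

    for dv in cfg.behavior_dvs:
        try_analyze(df, dv, short_slope=False, with_adptf=(dv != "AdpTF"),
                    run_posthoc=cfg.run_posthoc)
    if feats is not None:
        for ch in cfg.features.focus_channels:
            for bm in ("hbo", "hbr"):
                col = f"mean_{bm}_ch{ch}"
                if col in df.columns and df[col].notna().sum() > 10:
                    try_analyze(df, col, short_slope=True,
                                run_posthoc=cfg.run_posthoc)

    # RE/RI per focus channel and biomarker (scan-based performance),
    # Group + Group:Session structure with the extracerebral random slope
    eff_path = out / "efficiency.csv"
    if eff_path.exists():
        eff = pd.read_csv(eff_path)
        short = df[["ID", "Session", "subarea", "Short"]]
        for ch in cfg.features.focus_channels:
            for bm in ("hbo", "hbr"):
                sub = eff[(eff["channel"] == ch) & (eff["biomarker"] == bm)
                          & (eff["performance_measure"] == "scan")]
                if sub.empty:
                    continue
                sub = sub.rename(columns={"subject": "ID", "session": "Session"})
                sub = sub.merge(groups[["subject", "group"]].rename(
                    columns={"subject": "ID", "group": "Group"}), on="ID")
                sub = sub.merge(short, on=["ID", "Session", "subarea"], how="left")
                for m in ("RE", "RI"):
                    dv = f"{m}_{bm}_ch{ch}_scan"
                    frame = sub.rename(columns={m: dv})
                    if frame[dv].notna().sum() > 10:
                        try_analyze(frame, dv, short_slope=True,
                                    with_adptf=False,
                                    run_posthoc=cfg.run_posthoc)

    comp_rows, contrast_rows = [], []
    for an in analyses:
        for name, cmp_ in an.comparisons.items():
            comp_rows.append({
                "dv": an.dv, "comparison": name, "reduced": cmp_.reduced,
                "full": cmp_.full, "chi2": cmp_.chi2, "df": cmp_.df, "p": cmp_.p,
                "ll_reduced": an.fits[_reduced_key(name)].llf
                if _reduced_key(name) in an.fits else np.nan,
                "ll_full": an.fits[_full_key(name)].llf
                if _full_key(name) in an.fits else np.nan,
            })
        for c in an.contrasts:
            contrast_rows.append({"dv": an.dv, **c.__dict__})
    pd.DataFrame(comp_rows).to_csv(out / "model_comparisons.csv", index=False)
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)
    write_report(analyses, out / "report.txt")
    return {"model_comparisons": len(comp_rows), "contrasts": len(contrast_rows)}


def _reduced_key(name: str) -> str:
    return {"session_vs_null": "null", "group_session_vs_group": "group",
            "group_session_vs_session": "session",
            "adptf_vs_group_session": "group_session"}[name]


def _full_key(name: str) -> str:
    return {"session_vs_null": "session", "group_session_vs_group": "group_session",
            "group_session_vs_session": "group_session",
            "adptf_vs_group_session": "full_adptf"}[name]


def write_report(analyses: list[DVAnalysis], path: Path) -> None:
    """Human-readable goodness-of-fit table: log-likelihoods with and without
    the individual-differences factor, chi-square and p per comparison."""
    lines = ["Goodness-of-fit comparison of models with and without Group", "=" * 64]
    for an in analyses:
        lines.append(f"\nDV: {an.dv}")
        no = an.fits["session"]; yes = an.fits["group_session"]
        lines.append(f"  without Group  logLik {no.llf:10.2f}  ({no.spec.label()})")
        lines.append(f"  with Group     logLik {yes.llf:10.2f}  ({yes.spec.label()})")
        for name, cmp_ in an.comparisons.items():
            lines.append(f"  {name:28s} chi2({cmp_.df}) = {cmp_.chi2:7.2f}, p = {cmp_.p:.4g}")
        for note in an.notes:
            lines.append(f"  note: {note}")
        for c in an.contrasts:
            lines.append(f"    {c.label:30s} est {c.estimate:+.3f}  df {c.df:6.1f}  "
                         f"p {c.p:.4f}  adj.p {c.adj_p:.4f}  d {c.d:+.2f} ({c.band})")
    Path(path).write_text("\n".join(lines) + "\n")


STAGES = {
    "simulate": stage_simulate,
    "score": stage_score,
    "fnirs": stage_fnirs_features,
    "features": stage_efficiency,
    "group": stage_group,
    "model": stage_model,
}


def run(cfg: PipelineConfig, out_dir: str | Path, stages: list[str] | None = None) -> dict:
    """Execute the enabled stages in order and write the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = stages or [s for s, on in (
        ("simulate", cfg.run_behavior), ("score", cfg.run_behavior),
        ("fnirs", cfg.run_fnirs),
        ("features", cfg.run_fnirs and cfg.run_behavior),
        ("group", cfg.run_behavior),
        ("model", cfg.run_models)) if on]
    counts: dict[str, int] = {}
    for name in order:
        logger.info("stage %s", name)
        try:
            counts.update(STAGES[name](cfg, out))
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage {name!r}: missing upstream output {exc.filename}") from exc
    manifest = {
        "package_version": __version__,
        "seed": cfg.scenario.seed,
        "config_hash": cfg.digest(),
        "stages": order,
        "row_counts": counts,
        "output_hashes": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
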