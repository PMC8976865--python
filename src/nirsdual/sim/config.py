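"""Scenario and noise configuration for the synthetic dual-task study.

The defaults reproduce the study conditions: 13 subjects, three easy sessions
(E1--E3) and two hard ones (H1--H2), six ~2-min subareas per session with 10-s
gaps, a 10 Hz 18-channel prefrontal probe, and a 6/7 split into an
Attention-focused group (scan performance improves across easy sessions) and
an Accuracy-focused group (scan deteriorates while target-find improves).
Noise frequencies place respiration (0.25 Hz) and cardiac (1.1 Hz) components
above the 0.1 Hz low-pass cutoff so the preprocessing provably attenuates
them, and Mayer waves (0.1 Hz) at its edge.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..probe import N_CHANNELS, N_LONG

EASY_SESSIONS = ("E1", "E2", "E3")
HARD_SESSIONS = ("H1", "H2")
SESSIONS = EASY_SESSIONS + HARD_SESSIONS

GROUPS = ("attention", "accuracy")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise model. Oscillation/drift/spike amplitudes are expressed
    in uM on the HbO scale (HbR components are scaled by the HbR/HbO ratio);
    ADC quantities are in counts."""

    drift_amplitude: float = 0.5       # uM, RMS of slow drift
    drift_timescale: float = 300.0     # s, knot spacing of the drift process
    cardiac_freq: float = 1.1          # Hz
    cardiac_amp: float = 0.2           # uM
    resp_freq: float = 0.25            # Hz
    resp_amp: float = 0.15             # uM
    mayer_freq: float = 0.1            # Hz
    mayer_amp: float = 0.1             # uM
    white_sd: float = 0.05             # uM
    spike_rate: float = 0.5            # events/min
    spike_amplitude: float = 10.0      # multiples of the physiological SD
    extracerebral_gain: float = 0.3    # coupling of shared superficial signal into long channels
    extracerebral_amp: float = 0.8     # uM, scale of the shared superficial signal
    ambient_level: float = 400.0       # ADC counts of background light
    ambient_sd: float = 1.5            # ADC counts, shot noise of the ambient reading
    adc_noise_sd: float = 3.0          # ADC counts, per-wavelength measurement noise
    dark_current: float = 60.0         # ADC counts, per-channel scalar
    saturation_ceiling: float = 4500.0  # ADC counts

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "cardiac_amp", "resp_amp", "mayer_amp",
                     "white_sd", "spike_rate", "spike_amplitude",
                     "extracerebral_gain", "extracerebral_amp",
                     "ambient_level", "ambient_sd", "adc_noise_sd", "dark_current"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("cardiac_freq", "resp_freq", "mayer_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _default_groups(n_subjects: int) -> dict[str, str]:
    """6/7 attention/accuracy split at n=13; otherwise near-even split."""
    n_att = 6 if n_subjects == 13 else n_subjects // 2
    out = {}
    for i in range(n_subjects):
        out[f"S{i + 1:02d}"] = "attention" if i < n_att else "accuracy"
    return out


def default_effect_map(
    base_amp: float = 0.5,
    trend: float = 0.15,
    focus_channels: tuple[int, ...] = (2, 7, 12),
) -> dict[tuple[str, str], np.ndarray]:
    """Per-channel HRF amplitudes (uM, HbO scale) by (group, session).

    All long channels respond to the task at ``base_amp``. On the focus
    channels the groups diverge across easy sessions (practice decreases
    activity in the improving group's task-relevant channels and vice versa),
    and hard sessions hold the E3 level. Short channels carry no cortical
    response.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for group in GROUPS:
        sign = 1.0 if group == "attention" else -1.0
        for s_idx, session in enumerate(SESSIONS):
            easy_idx = min(s_idx, len(EASY_SESSIONS) - 1)
            amps = np.zeros(N_CHANNELS)
            amps[:N_LONG] = base_amp
            for ch in focus_channels:
                amps[ch - 1] = base_amp + sign * trend * easy_idx
            out[(group, session)] = amps
    return out


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that determines one synthetic study; ``seed`` fixes it all."""

    n_subjects: int = 13
    sessions: tuple[str, ...] = SESSIONS
    subareas_per_session: int = 6
    subarea_duration: float = 120.0   # s
    inter_subarea_gap: float = 10.0   # s
    fs: float = 10.0                  # Hz
    group_assignment: Mapping[str, str] | None = None
    scan_slope_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"attention": 0.1, "accuracy": -0.1})
    scan_base_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"attention": 0.45, "accuracy": 0.65})
    scan_noise_sd: float = 0.05       # subarea-level noise on the scan fraction
    subject_sd: float = 0.05          # between-subject intercept SD on scan
    over_scan_mean: float = 0.15
    over_scan_sd: float = 0.04
    target_rate: float = 0.8
    accuracy_base_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"attention": 0.6, "accuracy": 0.4})
    accuracy_slope_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"attention": 0.0, "accuracy": 0.15})
    hbr_ratio: float = 1.0 / 3.0      # |HbR| response as a fraction of HbO
    effect_map: Mapping[tuple[str, str], np.ndarray] | None = None
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.subarea_duration <= 30:
            raise ValueError("subarea_duration must exceed 30 s (epoch window non-empty)")
        if not 0 <= self.target_rate <= 1:
            raise ValueError("target_rate must be a probability")
        slopes = [self.scan_slope_by_group.get(g, 0.0) for g in GROUPS]
        if slopes[0] * slopes[1] > 0:
            raise ValueError("scan slopes for the two groups must have opposite signs")
        for g in self.groups().values():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")

    def groups(self) -> dict[str, str]:
        if self.group_assignment is not None:
            return dict(self.group_assignment)
        return _default_groups(self.n_subjects)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.groups().keys())

    def effects(self) -> Mapping[tuple[str, str], np.ndarray]:
        return self.effect_map if self.effect_map is not None else default_effect_map()

    def session_samples(self) -> int:
        n_sub = self.subareas_per_session
        dur = n_sub * self.subarea_duration + (n_sub - 1) * self.inter_subarea_gap
        return int(round(dur * self.fs))

    def subarea_onsets(self) -> np.ndarray:
        step = self.subarea_duration + self.inter_subarea_gap
        return np.arange(self.subareas_per_session) * step

    def rng(self, *stream: object) -> np.random.Generator:
        """Independent substream keyed by (seed, *stream) so each subject,
        session and purpose draws reproducibly regardless of iteration order.
        Uses crc32, not ``hash()``, so streams survive hash randomization."""
        key = [self.seed] + [zlib.crc32(str(s).encode()) for s in stream]
        return np.random.default_rng(np.random.SeedSequence(key))
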