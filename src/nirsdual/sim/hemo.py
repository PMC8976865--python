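"""Ground-truth hemodynamics: task boxcars convolved with a canonical HRF.

Each subarea contributes a boxcar regressor; convolution with a double-gamma
hemodynamic response function (normalized to unit area, so a sustained block
plateaus at the configured amplitude) yields the noise-free HbO trace per
channel. HbR ground truth is an inverted, scaled copy of HbO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .config import ScenarioConfig


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (s), unit area.

    Shape parameters follow the widely used peak-at-6-s / undershoot-at-16-s
    convention; the area normalization makes long-block convolution plateau
    at the regressor amplitude.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0

    def gamma_pdf(x, shape, scale):
        return np.exp((shape - 1) * np.log(x) - x / scale
                      - gammaln(shape) - shape * np.log(scale))

    a1 = peak_delay / dispersion
    a2 = undershoot_delay / undershoot_dispersion
    h[pos] = (gamma_pdf(t[pos], a1, dispersion)
              - undershoot_ratio * gamma_pdf(t[pos], a2, undershoot_dispersion))
    area = np.trapezoid(h, t)
    if abs(area) < 1e-12:
        raise ValueError("degenerate HRF: zero area")
    return h / area


def task_boxcar(cfg: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """(t, boxcar) for one session: 1 during subareas, 0 during gaps."""
    n = cfg.session_samples()
    t = np.arange(n) / cfg.fs
    box = np.zeros(n)
    for onset in cfg.subarea_onsets():
        box[(t >= onset) & (t < onset + cfg.subarea_duration)] = 1.0
    return t, box


@dataclass
class GroundTruth:
    subject: str
    session: str
    t: np.ndarray
    hbo: np.ndarray  # (n_channels, n_samples), uM
    hbr: np.ndarray
    subarea_onsets: np.ndarray
    subarea_duration: float


def simulate_session_hemodynamics(
    cfg: ScenarioConfig, subject: str, session: str
) -> GroundTruth:
    """Noise-free per-channel HbO/HbR for one subject x session."""
    groups = cfg.groups()
    if subject not in groups:
        raise ValueError(f"unknown subject {subject!r}")
    group = groups[subject]
    effects = cfg.effects()
    if (group, session) not in effects:
        raise ValueError(f"effect_map has no entry for ({group!r}, {session!r})")
    amps = np.asarray(effects[(group, session)], dtype=float)

    t, box = task_boxcar(cfg)
    t_hrf = np.arange(0, 32.0, 1.0 / cfg.fs)
    hrf = double_gamma_hrf(t_hrf)
    resp = np.convolve(box, hrf)[: len(box)] / cfg.fs

    hbo = amps[:, None] * resp[None, :]
    hbr = -cfg.hbr_ratio * hbo
    return GroundTruth(subject=subject, session=session, t=t, hbo=hbo, hbr=hbr,
                       subarea_onsets=cfg.subarea_onsets(),
                       subarea_duration=cfg.subarea_duration)


def simulate_hemodynamics(cfg: ScenarioConfig) -> dict[tuple[str, str], GroundTruth]:
    """Ground truth for every subject x session in the scenario."""
    return {
        (subj, sess): simulate_session_hemodynamics(cfg, subj, sess)
        for subj in cfg.subjects for sess in cfg.sessions
    }
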