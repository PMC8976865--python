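"""Forward optical model: concentrations -> raw ADC intensities, plus the
physiological/instrumental noise stack.

The forward map is the inverse of the modified Beer--Lambert law used in
preprocessing: dOD_lambda = (eps_HbO * dHbO + eps_HbR * dHbR) * d * DPF with
concentrations in mM, then I = I0 * 10^(-dOD), ambient background added,
quantization to integer counts, and clipping at the ADC ceiling.
"""

from __future__ import annotations

import numpy as np

from ..probe import ExtinctionTable, ProbeLayout, default_layout, WAVELENGTHS
from ..recording import RawRecording
from .config import NoiseConfig, ScenarioConfig
from .hemo import GroundTruth, simulate_session_hemodynamics

DEFAULT_I0 = {750: 1500.0, 830: 2000.0}  # ADC counts above background


def forward_mbll(
    hbo: np.ndarray,
    hbr: np.ndarray,
    layout: ProbeLayout | None = None,
    coeffs: ExtinctionTable | None = None,
    i0: dict[int, float] | None = None,
) -> dict[int, np.ndarray]:
    """Noise-free intensities per wavelength from uM concentration arrays.

    ``hbo``/``hbr`` are (n_channels, n_samples). Returns {wavelength: counts}
    as real-valued intensities (no background, no quantization) so the map is
    exactly invertible; :func:`simulate_recording` adds the ADC realism.
    """
    layout = layout or default_layout()
    coeffs = coeffs or ExtinctionTable()
    i0 = i0 or DEFAULT_I0
    hbo_mM = np.asarray(hbo, dtype=float) / 1000.0
    hbr_mM = np.asarray(hbr, dtype=float) / 1000.0
    d = np.array([ch.separation_cm for ch in layout.channels])[:, None]
    out: dict[int, np.ndarray] = {}
    for wl in WAVELENGTHS:
        dod = (coeffs.eps_hbo[wl] * hbo_mM + coeffs.eps_hbr[wl] * hbr_mM) * d * coeffs.dpf[wl]
        out[wl] = i0[wl] * 10.0 ** (-dod)
    return out


def _slow_process(rng: np.random.Generator, t: np.ndarray, timescale: float,
                  amplitude: float) -> np.ndarray:
    """Smooth drift: standard-normal knots every ``timescale`` s, linearly
    interpolated, scaled to the requested RMS amplitude."""
    if amplitude == 0:
        return np.zeros_like(t)
    knots_t = np.arange(0, t[-1] + 2 * timescale, timescale)
    knots = rng.standard_normal(len(knots_t))
    return amplitude * np.interp(t, knots_t, knots)


def _oscillation(rng: np.random.Generator, t: np.ndarray, freq: float,
                 amp: float) -> np.ndarray:
    phase = rng.uniform(0, 2 * np.pi)
    jitter = 1.0 + 0.02 * rng.standard_normal()
    return amp * np.sin(2 * np.pi * freq * jitter * t + phase)


def _spike_train(rng: np.random.Generator, t: np.ndarray, fs: float,
                 rate_per_min: float, amplitude: float, tau: float = 0.5) -> np.ndarray:
    out = np.zeros_like(t)
    n_events = rng.poisson(rate_per_min * t[-1] / 60.0)
    for _ in range(n_events):
        i0 = rng.integers(0, len(t))
        sign = rng.choice([-1.0, 1.0])
        length = int(5 * tau * fs)
        idx = np.arange(i0, min(i0 + length, len(t)))
        out[idx] += sign * amplitude * np.exp(-(idx - i0) / (tau * fs))
    return out


def physiological_noise(
    cfg: ScenarioConfig, subject: str, session: str, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Additive (hbo_noise, hbr_noise) in uM, shape (n_channels, n_samples).

    Includes drift, Mayer/respiratory/cardiac oscillations, white noise,
    occasional motion spikes, and a shared extracerebral component that
    enters short channels at unit gain and long channels at
    ``extracerebral_gain``.
    """
    nz: NoiseConfig = cfg.noise
    layout = default_layout()
    n_ch = len(layout.channels)
    hbo_n = np.zeros((n_ch, len(t)))

    # shared superficial signal for this session
    rng_shared = cfg.rng(subject, session, "extracerebral")
    shared = (_slow_process(rng_shared, t, nz.drift_timescale, nz.extracerebral_amp)
              + _oscillation(rng_shared, t, nz.mayer_freq, 0.5 * nz.extracerebral_amp))

    phys_sd = np.sqrt(nz.cardiac_amp**2 / 2 + nz.resp_amp**2 / 2
                      + nz.mayer_amp**2 / 2 + nz.white_sd**2)
    for j, ch in enumerate(layout.channels):
        rng = cfg.rng(subject, session, "noise", ch.index)
        x = _slow_process(rng, t, nz.drift_timescale, nz.drift_amplitude)
        x += _oscillation(rng, t, nz.cardiac_freq, nz.cardiac_amp)
        x += _oscillation(rng, t, nz.resp_freq, nz.resp_amp)
        x += _oscillation(rng, t, nz.mayer_freq, nz.mayer_amp)
        x += nz.white_sd * rng.standard_normal(len(t))
        x += _spike_train(rng, t, cfg.fs, nz.spike_rate,
                          nz.spike_amplitude * phys_sd)
        gain = 1.0 if ch.kind == "short" else nz.extracerebral_gain
        x += gain * shared
        hbo_n[j] = x
    hbr_n = -cfg.hbr_ratio * hbo_n
    return hbo_n, hbr_n


def simulate_recording(
    cfg: ScenarioConfig,
    subject: str,
    session: str,
    layout: ProbeLayout | None = None,
    coeffs: ExtinctionTable | None = None,
    noise_free: bool = False,
) -> tuple[RawRecording, GroundTruth]:
    """One subject x session raw recording plus its noise-free ground truth."""
    layout = layout or default_layout()
    coeffs = coeffs or ExtinctionTable()
    truth = simulate_session_hemodynamics(cfg, subject, session)
    t = truth.t
    nz = cfg.noise

    hbo, hbr = truth.hbo, truth.hbr
    if not noise_free:
        hbo_n, hbr_n = physiological_noise(cfg, subject, session, t)
        hbo = hbo + hbo_n
        hbr = hbr + hbr_n

    clean = forward_mbll(hbo, hbr, layout, coeffs)
    rng_adc = cfg.rng(subject, session, "adc")
    n_ch = len(layout.channels)
    # The background (ambient light + dark response) level is common to the
    # ambient reading and the signal readings, but the shot noise of each
    # reading is independent.
    background = nz.dark_current + nz.ambient_level
    if noise_free:
        ambient = np.full((n_ch, len(t)), background)
    else:
        ambient = background + nz.ambient_sd * rng_adc.standard_normal((n_ch, len(t)))
        ambient = np.clip(np.round(ambient), 0, nz.saturation_ceiling)

    rec_arrays = {}
    for wl in WAVELENGTHS:
        meas = clean[wl] + background
        if not noise_free:
            meas = np.round(meas + nz.adc_noise_sd
                            * rng_adc.standard_normal(meas.shape))
        rec_arrays[wl] = np.clip(meas, 0, nz.saturation_ceiling)

    dark = np.full(n_ch, nz.dark_current)
    rec = RawRecording(
        subject=subject, session=session, fs=cfg.fs, t=t,
        i750=rec_arrays[750], i830=rec_arrays[830], ambient=ambient,
        dark_current=dark, layout=layout,
        subarea_onsets=cfg.subarea_onsets(), subarea_duration=cfg.subarea_duration,
    )
    return rec, truth
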