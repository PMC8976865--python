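"""In-memory containers for raw optical recordings and processed hemodynamics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probe import ProbeLayout


@dataclass
class RawRecording:
    """Raw dual-wavelength intensities for one subject x session.

    Intensity arrays are shaped (n_channels, n_samples) in ADC counts.
    ``ambient`` is the no-illumination reading (background light + detector
    dark response) sampled on the same grid. ``dark_current`` is the
    per-channel scalar the device reports at calibration.
    """

    subject: str
    session: str
    fs: float
    t: np.ndarray
    i750: np.ndarray
    i830: np.ndarray
    ambient: np.ndarray
    dark_current: np.ndarray
    layout: ProbeLayout
    subarea_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    subarea_duration: float = 120.0

    def __post_init__(self) -> None:
        n_ch = len(self.layout.channels)
        for name in ("i750", "i830", "ambient"):
            arr = getattr(self, name)
            if arr.shape != (n_ch, len(self.t)):
                raise ValueError(
                    f"{name} must have shape ({n_ch}, {len(self.t)}), got {arr.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.any(self.i750 < 0) or np.any(self.i830 < 0):
            raise ValueError("intensities must be non-negative ADC counts")

    @property
    def n_channels(self) -> int:
        return len(self.layout.channels)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (time, channel, wavelength)."""
        rows = []
        for j, ch in enumerate(self.layout.channels):
            for wl, arr in ((750, self.i750), (830, self.i830), (0, self.ambient)):
                rows.append(pd.DataFrame({
                    "subject": self.subject, "session": self.session,
                    "t": self.t, "channel": ch.index, "wavelength": wl,
                    "intensity": arr[j],
                }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class QCMask:
    """Per-channel retention decisions for one recording."""

    subject: str
    session: str
    retained: np.ndarray          # bool, per channel
    reasons: list[str]            # "" if retained, else rejection reason

    REASONS = ("saturated", "dark_current", "ambient_corr")

    def __post_init__(self) -> None:
        if len(self.retained) != len(self.reasons):
            raise ValueError("retained/reasons length mismatch")
        for ok, why in zip(self.retained, self.reasons):
            if not ok and why not in self.REASONS:
                raise ValueError(f"unknown rejection reason {why!r}")

    @property
    def n_retained(self) -> int:
        return int(np.sum(self.retained))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject, "session": self.session,
            "channel": np.arange(1, len(self.retained) + 1),
            "retained": self.retained, "reason": self.reasons,
        })


@dataclass
class HemoTimeSeries:
    """Per-channel oxy/deoxyhemoglobin concentration changes in micromolar.

    Rejected channels carry NaN rows; ``qc`` records why.
    """

    subject: str
    session: str
    fs: float
    t: np.ndarray
    hbo: np.ndarray  # (n_channels, n_samples), uM
    hbr: np.ndarray
    qc: QCMask
    provenance: list[str] = field(default_factory=list)
    subarea_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    subarea_duration: float = 120.0

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape or self.hbo.shape[1] != len(self.t):
            raise ValueError("hbo/hbr must be (n_channels, n_samples) matching t")

    def to_frame(self) -> pd.DataFrame:
        n_ch = self.hbo.shape[0]
        frames = []
        for j in range(n_ch):
            frames.append(pd.DataFrame({
                "subject": self.subject, "session": self.session,
                "channel": j + 1, "t": self.t,
                "hbo_uM": self.hbo[j], "hbr_uM": self.hbr[j],
            }))
        return pd.concat(frames, ignore_index=True)
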