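"""Probe geometry and optical constants for a prefrontal continuous-wave fNIRS sensor.

The default layout models a 4-source / 12-detector prefrontal band sampled at
10 Hz: sixteen long source--detector separation (SDS) channels at 2.5 cm that
sample cortical tissue, and two short SDS channels at 1.0 cm (channels 17 and
18, under the middle two sources) that sample extracerebral tissue only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WAVELENGTHS = (750, 830)  # nm

N_LONG = 16
N_SHORT = 2
N_CHANNELS = N_LONG + N_SHORT

LONG_SEPARATION_CM = 2.5
SHORT_SEPARATION_CM = 1.0


@dataclass(frozen=True)
class ChannelSpec:
    """One source--detector pair."""

    index: int  # 1-based, 1..16 long, 17..18 short
    source: int
    detector: int
    separation_cm: float
    kind: str  # "long" | "short"

    def __post_init__(self) -> None:
        if self.kind not in ("long", "short"):
            raise ValueError(f"channel kind must be 'long' or 'short', got {self.kind!r}")
        if self.separation_cm <= 0:
            raise ValueError("separation must be positive")


@dataclass(frozen=True)
class ProbeLayout:
    """Source/detector positions plus the channel list.

    Positions are planar (x, y) in cm on the forehead; they matter only for
    bookkeeping and export, not for the Beer--Lambert inversion, which uses
    the per-channel separation.
    """

    sources: dict[int, tuple[float, float]]
    detectors: dict[int, tuple[float, float]]
    channels: tuple[ChannelSpec, ...]

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch.source not in self.sources:
                raise ValueError(f"channel {ch.index} references unknown source {ch.source}")
            if ch.detector not in self.detectors:
                raise ValueError(f"channel {ch.index} references unknown detector {ch.detector}")

    @property
    def long_channels(self) -> tuple[ChannelSpec, ...]:
        return tuple(c for c in self.channels if c.kind == "long")

    @property
    def short_channels(self) -> tuple[ChannelSpec, ...]:
        return tuple(c for c in self.channels if c.kind == "short")

    def channel(self, index: int) -> ChannelSpec:
        for c in self.channels:
            if c.index == index:
                return c
        raise KeyError(f"no channel with index {index}")


def default_layout() -> ProbeLayout:
    """The 18-channel prefrontal layout: 16 long channels (4 per source),
    and 2 short channels under the middle two sources."""
    sources = {i + 1: (float(6 * i), 0.0) for i in range(4)}
    detectors: dict[int, tuple[float, float]] = {}
    channels: list[ChannelSpec] = []
    det_id = 1
    idx = 1
    # 4 long detectors around each source, 2.5 cm away
    for s in range(1, 5):
        sx, sy = sources[s]
        for k, (dx, dy) in enumerate([(-2.5, 0.0), (0.0, 2.5), (0.0, -2.5), (2.5, 0.0)]):
            detectors[det_id] = (sx + dx, sy + dy)
            channels.append(
                ChannelSpec(index=idx, source=s, detector=det_id,
                            separation_cm=LONG_SEPARATION_CM, kind="long")
            )
            det_id += 1
            idx += 1
    # short detectors 1 cm from the middle two sources (2 and 3)
    for s in (2, 3):
        sx, sy = sources[s]
        detectors[det_id] = (sx + 1.0, sy)
        channels.append(
            ChannelSpec(index=idx, source=s, detector=det_id,
                        separation_cm=SHORT_SEPARATION_CM, kind="short")
        )
        det_id += 1
        idx += 1
    return ProbeLayout(sources=sources, detectors=detectors, channels=tuple(channels))


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients (1/(mM*cm)) and differential pathlength factors.

    Defaults are the standard compiled hemoglobin spectra values at 750 and
    830 nm (molar extinction / 1000 per mM) with DPF 6.0 at both wavelengths.
    Downstream z-standardization absorbs the per-channel scale these induce,
    so analysis conclusions are insensitive to the exact table; it is fully
    overridable regardless.
    """

    eps_hbo: dict[int, float] = field(
        default_factory=lambda: {750: 0.5179, 830: 0.9740})
    eps_hbr: dict[int, float] = field(
        default_factory=lambda: {750: 1.4066, 830: 0.6930})
    dpf: dict[int, float] = field(default_factory=lambda: {750: 6.0, 830: 6.0})

    def __post_init__(self) -> None:
        for wl in WAVELENGTHS:
            for table in (self.eps_hbo, self.eps_hbr, self.dpf):
                if wl not in table:
                    raise ValueError(f"missing value for wavelength {wl} nm")
                if table[wl] <= 0:
                    raise ValueError("extinction coefficients and DPF must be positive")
        if abs(np.linalg.det(self.matrix())) < 1e-12:
            raise ValueError("extinction matrix is singular; chromophores not separable")

    def matrix(self) -> np.ndarray:
        """Rows = wavelengths (750, 830); columns = (HbO, HbR)."""
        return np.array(
            [[self.eps_hbo[wl], self.eps_hbr[wl]] for wl in WAVELENGTHS]
        )

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix())
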