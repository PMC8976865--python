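"""Minimal SNIRF (HDF5) export/import for raw recordings.

Writes the subset of the SNIRF layout needed to round-trip our continuous-
wave recordings: /nirs/data1/dataTimeSeries with one measurementList entry
per (channel, wavelength), probe source/detector 2-D positions, and the
ambient trace as an auxiliary ("aux") group. This is a purpose-built writer,
not a full implementation of the format.
"""

from __future__ import annotations

import numpy as np
import h5py

from .probe import ChannelSpec, ProbeLayout, WAVELENGTHS
from .recording import RawRecording


def write_snirf(rec: RawRecording, path: str) -> None:
    layout = rec.layout
    n_ch = rec.n_channels
    wl_list = list(WAVELENGTHS)
    series = np.empty((len(rec.t), n_ch * len(wl_list)))
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=np.bytes_(rec.subject))
        meta.create_dataset("SessionID", data=np.bytes_(rec.session))
        meta.create_dataset("LengthUnit", data=np.bytes_("cm"))
        meta.create_dataset("TimeUnit", data=np.bytes_("s"))

        data = nirs.create_group("data1")
        k = 0
        for j, ch in enumerate(layout.channels):
            for wi, wl in enumerate(wl_list, start=1):
                arr = rec.i750 if wl == 750 else rec.i830
                series[:, k] = arr[j]
                ml = data.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=ch.source)
                ml.create_dataset("detectorIndex", data=ch.detector)
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=ch.index)
                k += 1
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=rec.t)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(wl_list, dtype=float))
        src = np.array([layout.sources[i] for i in sorted(layout.sources)])
        det = np.array([layout.detectors[i] for i in sorted(layout.detectors)])
        probe.create_dataset("sourcePos2D", data=src)
        probe.create_dataset("detectorPos2D", data=det)

        aux = nirs.create_group("aux1")
        aux.create_dataset("name", data=np.bytes_("ambient"))
        aux.create_dataset("dataTimeSeries", data=rec.ambient.T)
        aux.create_dataset("time", data=rec.t)
        aux2 = nirs.create_group("aux2")
        aux2.create_dataset("name", data=np.bytes_("dark_current"))
        aux2.create_dataset("dataTimeSeries", data=rec.dark_current)


def read_snirf(path: str) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        subject = nirs["metaDataTags/SubjectID"][()].decode()
        session = nirs["metaDataTags/SessionID"][()].decode()
        t = np.asarray(nirs["data1/time"])
        series = np.asarray(nirs["data1/dataTimeSeries"])
        wl = [int(w) for w in np.asarray(nirs["probe/wavelengths"])]

        src_pos = np.asarray(nirs["probe/sourcePos2D"])
        det_pos = np.asarray(nirs["probe/detectorPos2D"])
        sources = {i + 1: tuple(p) for i, p in enumerate(src_pos)}
        detectors = {i + 1: tuple(p) for i, p in enumerate(det_pos)}

        n_meas = series.shape[1]
        per_ch: dict[int, dict[int, np.ndarray]] = {}
        chans: dict[int, ChannelSpec] = {}
        for k in range(n_meas):
            ml = nirs[f"data1/measurementList{k + 1}"]
            s, d = int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()])
            idx = int(ml["dataTypeIndex"][()])
            wavelength = wl[int(ml["wavelengthIndex"][()]) - 1]
            sep = float(np.hypot(*(np.array(sources[s]) - np.array(detectors[d]))))
            kind = "short" if sep < 1.75 else "long"
            chans.setdefault(idx, ChannelSpec(index=idx, source=s, detector=d,
                                              separation_cm=round(sep, 3), kind=kind))
            per_ch.setdefault(idx, {})[wavelength] = series[:, k]
        layout = ProbeLayout(sources=sources, detectors=detectors,
                             channels=tuple(chans[i] for i in sorted(chans)))
        n_ch = len(layout.channels)
        i750 = np.vstack([per_ch[c.index][750] for c in layout.channels])
        i830 = np.vstack([per_ch[c.index][830] for c in layout.channels])
        ambient = np.asarray(nirs["aux1/dataTimeSeries"]).T
        dark = np.asarray(nirs["aux2/dataTimeSeries"])
        fs = float(1.0 / np.median(np.diff(t))) if len(t) > 1 else 10.0
    return RawRecording(subject=subject, session=session, fs=fs, t=t,
                        i750=i750, i830=i830, ambient=ambient,
                        dark_current=dark, layout=layout)
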