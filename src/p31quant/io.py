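"""Container I/O: HDF5 signal bundles and two-column text spectra.

The HDF5 layout stores one complex dataset per signal under ``/signals``
with acquisition parameters as root attributes and per-signal provenance
attributes.  Single spectra can also be exchanged as jMRUI-style text: a
small ``key: value`` header followed by two whitespace-separated columns of
real and imaginary FID samples.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .core import FID, AcquisitionParams

__all__ = ["save_signals", "load_signals", "write_jmrui_txt", "read_jmrui_txt"]


def save_signals(path: str | Path, fids: list[FID]) -> None:
    if not fids:
        raise ValueError("no signals to save")
    acq = fids[0].acq
    with h5py.File(path, "w") as fh:
        fh.attrs["dwell_time"] = acq.dwell_time
        fh.attrs["n_points"] = acq.n_points
        fh.attrs["reference_frequency"] = acq.reference_frequency
        fh.attrs["tr"] = acq.tr
        fh.attrs["flip_angle"] = acq.flip_angle
        grp = fh.create_group("signals")
        for i, fid in enumerate(fids):
            ds = grp.create_dataset(f"{i:05d}", data=fid.samples)
            ds.attrs["provenance"] = fid.provenance


def load_signals(path: str | Path) -> list[FID]:
    with h5py.File(path, "r") as fh:
        acq = AcquisitionParams(
            dwell_time=float(fh.attrs["dwell_time"]),
            n_points=int(fh.attrs["n_points"]),
            reference_frequency=float(fh.attrs["reference_frequency"]),
            tr=float(fh.attrs["tr"]),
            flip_angle=float(fh.attrs["flip_angle"]),
        )
        out = []
        for key in sorted(fh["signals"]):
            ds = fh["signals"][key]
            out.append(FID(samples=ds[()], acq=acq, provenance=ds.attrs.get("provenance", "")))
    return out


def write_jmrui_txt(fid: FID, path: str | Path) -> None:
    """Two-column real/imaginary text export of a single FID."""
    header = [
        f"PointsInDataset: {len(fid)}",
        f"SamplingInterval_ms: {fid.acq.dwell_time * 1e3:.9g}",
        f"TransmitterFrequency_MHz: {fid.acq.reference_frequency:.9g}",
        "Columns: sig_real sig_imag",
    ]
    body = "\n".join(f"{s.real:.9e}\t{s.imag:.9e}" for s in fid.samples)
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


def read_jmrui_txt(path: str | Path, acq: AcquisitionParams | None = None) -> FID:
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    data = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if ":" in line and not line.split(":", 1)[0].lstrip("-+").replace(".", "").isdigit():
            key, value = line.split(":", 1)
            meta[key.strip()] = value.strip()
        else:
            parts = line.split()
            if len(parts) >= 2:
                data.append(complex(float(parts[0]), float(parts[1])))
    if not data:
        raise ValueError(f"no samples found in {path}")
    if acq is None:
        dwell = float(meta.get("SamplingInterval_ms", 0.25)) * 1e-3
        acq = AcquisitionParams(
            dwell_time=dwell,
            n_points=len(data),
            reference_frequency=float(meta.get("TransmitterFrequency_MHz", 120.6)),
        )
    return FID(samples=np.array(data), acq=acq, provenance=str(path))
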