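"""Reading and writing the pipeline's file formats.

Reflectance stacks travel as multi-frame TIFF (frame order time-major,
wavelength-minor) or HDF5, each with a JSON sidecar carrying wavelengths,
frame rate, pixel pitch and the optical-density log convention (natural
log). Electrophysiology goes to HDF5 with one dataset per channel.
Haemoglobin series go to HDF5 (one dataset per component) and ROI-level
series additionally to CSV. Masks are 2-D binary rasters (PNG or HDF5).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .containers import BaselineState, HaemSeries, ReflectanceStack
from .mua import ElectrodeRecording, MUASeries

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_stack_h5",
    "read_stack_h5",
    "write_haem_h5",
    "read_haem_h5",
    "write_roi_csv",
    "write_ephys_h5",
    "read_ephys_h5",
    "write_mua_csv",
    "write_mask_png",
    "read_mask_png",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _stack_meta(stack: ReflectanceStack) -> dict:
    return {
        "wavelengths_nm": stack.wavelengths_nm.tolist(),
        "frame_rate_hz": stack.frame_rate,
        "pixel_pitch_um": stack.pixel_pitch_um,
        "frame_order": "time-major, wavelength-minor",
        "log_base": "natural",
        **{k: v for k, v in stack.meta.items() if isinstance(v, (int, float, str, bool))},
    }


def write_stack_tiff(path: str | Path, stack: ReflectanceStack) -> None:
    """Multi-frame TIFF: page t*n_wavelengths + j holds (time t, wavelength j)."""
    path = Path(path)
    T, H, W, L = stack.frames.shape
    pages = np.moveaxis(stack.frames, 3, 1).reshape(T * L, H, W).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(_stack_meta(stack), indent=2))


def read_stack_tiff(path: str | Path) -> ReflectanceStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path)
    lam = np.asarray(meta["wavelengths_nm"], dtype=float)
    L = lam.size
    T = pages.shape[0] // L
    frames = np.moveaxis(pages.reshape(T, L, *pages.shape[1:]), 1, 3)
    return ReflectanceStack(
        frames=frames,
        wavelengths_nm=lam,
        frame_rate=meta["frame_rate_hz"],
        pixel_pitch_um=meta.get("pixel_pitch_um", 75.0),
        meta=meta,
    )


def write_stack_h5(path: str | Path, stack: ReflectanceStack) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("reflectance", data=stack.frames)
        d.attrs["axes"] = "time,row,col,wavelength"
        f.create_dataset("wavelengths_nm", data=stack.wavelengths_nm)
        f.attrs["frame_rate_hz"] = stack.frame_rate
        f.attrs["pixel_pitch_um"] = stack.pixel_pitch_um
        f.attrs["log_base"] = "natural"


def read_stack_h5(path: str | Path) -> ReflectanceStack:
    with h5py.File(path, "r") as f:
        return ReflectanceStack(
            frames=f["reflectance"][()],
            wavelengths_nm=f["wavelengths_nm"][()],
            frame_rate=float(f.attrs["frame_rate_hz"]),
            pixel_pitch_um=float(f.attrs.get("pixel_pitch_um", 75.0)),
        )


def write_haem_h5(path: str | Path, h: HaemSeries) -> None:
    with h5py.File(path, "w") as f:
        for name in ("hbt", "hbo", "hbr"):
            f.create_dataset(name, data=getattr(h, name))
        f.attrs["mode"] = h.mode
        f.attrs["frame_rate_hz"] = h.frame_rate
        f.attrs["c_hbt0_uM"] = h.baseline.c_hbt0
        f.attrs["s0"] = h.baseline.s0
        if h.pixel_pitch_um:
            f.attrs["pixel_pitch_um"] = h.pixel_pitch_um


def read_haem_h5(path: str | Path) -> HaemSeries:
    with h5py.File(path, "r") as f:
        return HaemSeries(
            hbt=f["hbt"][()],
            hbo=f["hbo"][()],
            hbr=f["hbr"][()],
            frame_rate=float(f.attrs["frame_rate_hz"]),
            mode=str(f.attrs["mode"]),
            baseline=BaselineState(float(f.attrs["c_hbt0_uM"]), float(f.attrs["s0"])),
            pixel_pitch_um=float(f.attrs["pixel_pitch_um"]) if "pixel_pitch_um" in f.attrs else None,
        )


def write_roi_csv(path: str | Path, h: HaemSeries) -> None:
    """ROI-level series to CSV with columns time_s, hbt, hbo, hbr."""
    frac = h.to_fractional()
    if frac.hbt.ndim != 1:
        raise ValueError("write_roi_csv expects an ROI-level series")
    pd.DataFrame(
        {"time_s": frac.times, "hbt": frac.hbt, "hbo": frac.hbo, "hbr": frac.hbr}
    ).to_csv(path, index=False)


def write_ephys_h5(path: str | Path, rec: ElectrodeRecording) -> None:
    with h5py.File(path, "w") as f:
        for ch in range(rec.n_channels):
            f.create_dataset(f"channel_{ch:02d}", data=rec.traces[ch])
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        f.attrs["channel_spacing_um"] = rec.channel_spacing_um
        f.attrs["n_channels"] = rec.n_channels


def read_ephys_h5(path: str | Path) -> ElectrodeRecording:
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_channels"])
        traces = np.stack([f[f"channel_{ch:02d}"][()] for ch in range(n)])
        return ElectrodeRecording(
            traces=traces,
            sampling_rate=float(f.attrs["sampling_rate_hz"]),
            channel_spacing_um=float(f.attrs["channel_spacing_um"]),
        )


def write_mua_csv(path: str | Path, mua: MUASeries) -> None:
    """Long-format CSV: bin_start_s, channel, count, fractional."""
    n_ch, n_bins = mua.counts.shape
    pd.DataFrame(
        {
            "bin_start_s": np.tile(mua.bin_starts, n_ch),
            "channel": np.repeat(np.arange(n_ch), n_bins),
            "count": mua.counts.ravel(),
            "fractional": mua.fractional.ravel(),
        }
    ).to_csv(path, index=False)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 127
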