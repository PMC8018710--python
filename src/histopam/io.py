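"""On-disk containers: HDF5/CSV channel data, PNG masks and map previews
with JSON sidecars, CSV/JSON plans and reports."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .images import BinaryMask, GrayscaleImage
from .pam import AcousticPowerMap, ChannelData


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# ---------------------------------------------------------------- channel data

def save_channel_data(path, data: ChannelData, element_positions=None) -> None:
    """HDF5 container: dataset /samples (elements x time) with attributes
    sampling_rate, t0, frame_id and optional element_positions."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=data.samples)
        ds.attrs["sampling_rate"] = data.sampling_rate
        ds.attrs["t0"] = data.t0
        ds.attrs["frame_id"] = data.frame_id
        if element_positions is not None:
            f.create_dataset("element_positions", data=np.asarray(element_positions))


def load_channel_data(path) -> tuple[ChannelData, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        data = ChannelData(
            samples=ds[()],
            sampling_rate=float(ds.attrs["sampling_rate"]),
            t0=float(ds.attrs.get("t0", 0.0)),
            frame_id=int(ds.attrs.get("frame_id", 0)),
        )
        pos = f["element_positions"][()] if "element_positions" in f else None
    return data, pos


def save_channel_data_csv(path, data: ChannelData) -> None:
    """Plain-text fallback for toy cases: one row per element."""
    df = pd.DataFrame(data.samples)
    df.insert(0, "element", np.arange(data.n_elements))
    df.to_csv(path, index=False)
    _sidecar(Path(path)).write_text(
        json.dumps({"sampling_rate": data.sampling_rate, "t0": data.t0,
                    "frame_id": data.frame_id})
    )


def load_channel_data_csv(path) -> ChannelData:
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(Path(path)).read_text())
    samples = df.drop(columns=["element"]).to_numpy(dtype=float)
    return ChannelData(samples=samples, sampling_rate=meta["sampling_rate"],
                       t0=meta.get("t0", 0.0), frame_id=meta.get("frame_id", 0))


# --------------------------------------------------------------- masks/images

def save_mask_png(path, mask: BinaryMask) -> None:
    """1-bit PNG plus a JSON sidecar carrying spacing/origin in mm."""
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    _sidecar(Path(path)).write_text(
        json.dumps({"spacing_mm": mask.spacing.tolist(),
                    "origin_mm": mask.origin.tolist()})
    )


def load_mask_png(path) -> BinaryMask:
    px = np.asarray(iio.imread(path)) > 127
    sc = _sidecar(Path(path))
    meta = json.loads(sc.read_text()) if sc.exists() else {}
    return BinaryMask(
        px,
        np.asarray(meta.get("spacing_mm", [1.0, 1.0])),
        np.asarray(meta.get("origin_mm", [0.0, 0.0])),
    )


def save_image_tiff(path, image: GrayscaleImage) -> None:
    import tifffile

    tifffile.imwrite(path, image.pixels.astype(np.float32))
    _sidecar(Path(path)).write_text(
        json.dumps({"spacing_mm": image.spacing.tolist(),
                    "origin_mm": image.origin.tolist()})
    )


def load_image_tiff(path) -> GrayscaleImage:
    import tifffile

    px = tifffile.imread(path)
    sc = _sidecar(Path(path))
    meta = json.loads(sc.read_text()) if sc.exists() else {}
    return GrayscaleImage(
        px,
        np.asarray(meta.get("spacing_mm", [1.0, 1.0])),
        np.asarray(meta.get("origin_mm", [0.0, 0.0])),
    )


# ----------------------------------------------------------------------- maps

def save_map(path, pmap: AcousticPowerMap) -> None:
    """Array container (.npy) with a JSON sidecar (grid, frames averaged)."""
    np.save(path, pmap.power)
    _sidecar(Path(path)).write_text(
        json.dumps({
            "azimuth_mm": pmap.azimuth_mm.tolist(),
            "range_mm": pmap.range_mm.tolist(),
            "frames_averaged": pmap.frames_averaged,
        })
    )


def load_map(path) -> AcousticPowerMap:
    power = np.load(path)
    meta = json.loads(_sidecar(Path(path)).read_text())
    return AcousticPowerMap(
        np.asarray(meta["azimuth_mm"]), np.asarray(meta["range_mm"]),
        power, frames_averaged=meta.get("frames_averaged", 1),
    )


def save_map_preview_png(path, pmap: AcousticPowerMap, dynamic_range_db=30.0):
    """8-bit PNG preview on a dB colormap."""
    from matplotlib import colormaps

    pk = pmap.power.max()
    if pk <= 0:
        img = np.zeros(pmap.power.shape)
    else:
        db = 10 * np.log10(np.maximum(pmap.power, pk * 1e-12) / pk)
        img = np.clip(1 + db / dynamic_range_db, 0, 1)
    rgba = colormaps["inferno"](img.T)      # range vertical, azimuth horizontal
    iio.imwrite(path, (rgba[..., :3] * 255).astype(np.uint8))


# ------------------------------------------------------------ plans & reports

def save_plan_csv(path, plan) -> None:
    df = pd.DataFrame(plan.stops, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "index", np.arange(plan.n_stops))
    df.to_csv(path, index=False)


def load_waypoints_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in ("x_mm", "y_mm", "z_mm") if c in df.columns]
    return df[cols].to_numpy(dtype=float)


def save_fiducials_csv(path, fiducials: np.ndarray, labels=None) -> None:
    fid = np.atleast_2d(fiducials)
    labels = labels or [f"F{i}" for i in range(fid.shape[0])]
    pd.DataFrame(
        {"label": labels, "x_mm": fid[:, 0], "y_mm": fid[:, 1]}
    ).to_csv(path, index=False)


def load_fiducials_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_mm", "y_mm"]].to_numpy(dtype=float)


def save_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
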