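"""Reading and writing movies, masks, labels and tables.

Movies are stored as HDF5 (dataset ``movie`` or ``events``, T×H×W,
attribute ``frame_rate_hz``) or TIFF stacks (frame rate in the ImageJ
metadata when writing; pass ``frame_rate`` explicitly when reading a
TIFF without one).  Masks are PNG (0/255) or HDF5 boolean; cascade and
metric tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Mask, PointProcessMovie, VoltageMovie

__all__ = [
    "save_movie",
    "load_movie",
    "save_point_process",
    "load_point_process",
    "save_labels",
    "load_labels",
    "save_mask",
    "load_mask",
    "cascades_to_frame",
    "events_to_table",
]


def _is_h5(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5"}


def save_movie(path, movie: VoltageMovie) -> None:
    path = Path(path)
    if _is_h5(path):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("movie", data=movie.data.astype(np.float32))
            d.attrs["frame_rate_hz"] = movie.frame_rate
            if movie.pixel_size_um is not None:
                d.attrs["pixel_size_um"] = movie.pixel_size_um
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(
            path,
            movie.data.astype(np.float32),
            imagej=True,
            metadata={"fps": movie.frame_rate, "axes": "TYX"},
        )
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")


def load_movie(path, frame_rate: float | None = None) -> VoltageMovie:
    path = Path(path)
    if _is_h5(path):
        with h5py.File(path, "r") as f:
            d = f["movie"]
            data = d[...]
            fr = float(d.attrs.get("frame_rate_hz", frame_rate or 0))
            px = d.attrs.get("pixel_size_um")
            px = float(px) if px is not None else None
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.imagej_metadata or {}
            fr = float(meta.get("fps", frame_rate or 0))
            px = None
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")
    if fr <= 0:
        raise ValueError("frame rate not stored in file; pass frame_rate=")
    return VoltageMovie(np.asarray(data, dtype=np.float64), fr, pixel_size_um=px)


def save_point_process(path, pp: PointProcessMovie) -> None:
    path = Path(path)
    if _is_h5(path):
        with h5py.File(path, "w") as f:
            d = f.create_dataset(
                "events", data=pp.events.astype(np.uint8), compression="gzip"
            )
            d.attrs["frame_rate_hz"] = pp.frame_rate
            if pp.threshold_sd is not None:
                d.attrs["threshold_sd"] = pp.threshold_sd
            if pp.mask is not None:
                f.create_dataset("mask", data=pp.mask.include.astype(np.uint8))
    elif path.suffix.lower() == ".csv":
        events_to_table(pp).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported point-process format: {path.suffix}")


def load_point_process(path, frame_rate: float | None = None) -> PointProcessMovie:
    path = Path(path)
    if not _is_h5(path):
        raise ValueError("point-process loading is HDF5 only (CSV is export-only)")
    with h5py.File(path, "r") as f:
        d = f["events"]
        events = d[...].astype(bool)
        fr = float(d.attrs.get("frame_rate_hz", frame_rate or 0))
        thr = d.attrs.get("threshold_sd")
        mask = None
        if "mask" in f:
            mask = Mask(f["mask"][...].astype(bool), provenance="combined")
    if fr <= 0:
        raise ValueError("frame rate not stored in file; pass frame_rate=")
    return PointProcessMovie(
        events, fr, mask=mask, threshold_sd=float(thr) if thr is not None else None
    )


def save_labels(path, labels: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=labels.astype(np.int32), compression="gzip")


def load_labels(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["labels"][...]


def save_mask(path, mask: Mask) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (mask.include.astype(np.uint8) * 255))
    elif _is_h5(path):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("mask", data=mask.include.astype(np.uint8))
            d.attrs["provenance"] = mask.provenance
    else:
        raise ValueError(f"unsupported mask format: {path.suffix}")


def load_mask(path) -> Mask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return Mask(arr > 127, provenance="manual")
    if _is_h5(path):
        with h5py.File(path, "r") as f:
            d = f["mask"]
            return Mask(d[...].astype(bool), provenance=d.attrs.get("provenance", "manual"))
    raise ValueError(f"unsupported mask format: {path.suffix}")


def cascades_to_frame(cascades) -> pd.DataFrame:
    """Cascade list → tidy table (cascade_id, t_start, t_end, size, truncated)."""
    return pd.DataFrame(
        [
            {
                "cascade_id": c.cascade_id,
                "t_start": c.t_start,
                "t_end": c.t_end,
                "size": c.size,
                "truncated": c.truncated,
            }
            for c in cascades
        ]
    )


def events_to_table(pp: PointProcessMovie) -> pd.DataFrame:
    """Sparse event table (t, y, x) of a point process."""
    t, y, x = np.nonzero(pp.events)
    return pd.DataFrame({"t": t, "y": y, "x": x})
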