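"""Readers and writers for every file the pipeline touches.

TIFF stacks carry one page per channel (or per frame for time lapses);
calibration (pixel size, channel names, frame interval) that TIFF tags do
not reliably carry lives in a YAML sidecar written next to the image.  All
tabular data use headered, comma-separated UTF-8 CSV.  Every writer/reader
pair is a lossless round trip on valid data.

CSV dialects (column order is fixed):

* polylines:  filopodium_id, vertex_index, x_px, y_px       (tip first)
* profiles:   filopodium_id, channel, sample_index, distance_um, intensity,
              pixel_size_um                                 (sample 0 = tip)
* titration:  l0_molar, signal  (+ a0_molar, constant per file)
* gold:       label, distance_nm
* flow:       cell_id, stain, intensity, condition
* ct:         gene, sample, ct
* spots:      frame, x_um, y_um, spot_id
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .binding import Titration
from .distributions import GoldParticleSet
from .errors import ArgumentError, CalibrationError, ParseError
from .profiles import ProfileRecord

log = logging.getLogger("filotip")

UINT16_MAX = 65535


@dataclass
class ImageStack:
    """A calibrated multichannel (and optionally multi-frame) image.

    ``pixels`` has shape (channels, y, x) or (channels, t, y, x), uint16.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size: float              # um / pixel
    frame_interval: float | None = None  # seconds, time lapse only

    def __post_init__(self) -> None:
        if self.pixels.ndim not in (3, 4):
            raise ArgumentError("pixels must be (c, y, x) or (c, t, y, x)")
        if self.pixels.dtype != np.uint16:
            raise ArgumentError("pixels must be uint16")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ArgumentError("channel_names must match the channel axis")
        if self.pixel_size <= 0:
            raise ArgumentError("pixel_size must be > 0")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.pixels[self.channel_names.index(name)]
        except ValueError:
            raise ArgumentError(f"no channel named {name!r}") from None


@dataclass
class PolylineAnnotation:
    """Ordered tip-first vertices (x, y in pixels) of one filopodium trace."""

    filopodium_id: str | int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ArgumentError("a polyline needs >= 2 (x, y) vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ArgumentError("consecutive vertices must be distinct")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multipage TIFF plus a YAML calibration sidecar."""
    path = Path(path)
    pages = stack.pixels.reshape((-1,) + stack.pixels.shape[-2:])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_size_um": float(stack.pixel_size),
        "channel_names": list(stack.channel_names),
        "frame_interval_s": None if stack.frame_interval is None else float(stack.frame_interval),
        "shape": list(stack.pixels.shape),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta), encoding="utf-8")


def read_image(
    path: str | Path,
    pixel_size: float | None = None,
    channel_names: list[str] | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a TIFF stack; calibration comes from the sidecar or arguments.

    Non-16-bit pixel data are converted with a warning: 8-bit values are
    scaled by 257 onto the 16-bit range, anything else is linearly rescaled
    to [0, 65535].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    pixels = tifffile.imread(path)
    side = _sidecar(path)
    meta = yaml.safe_load(side.read_text(encoding="utf-8")) if side.exists() else {}

    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        raise CalibrationError(
            f"{path}: no pixel size in sidecar; pass pixel_size explicitly"
        )
    if frame_interval is None:
        frame_interval = meta.get("frame_interval_s")

    shape = meta.get("shape")
    if shape is not None:
        pixels = pixels.reshape(shape)
    elif pixels.ndim == 2:
        pixels = pixels[None]
    if channel_names is None:
        channel_names = meta.get("channel_names") or [
            f"ch{i}" for i in range(pixels.shape[0])
        ]

    if pixels.dtype == np.uint8:
        warnings.warn(f"{path}: 8-bit input scaled x257 to 16-bit", stacklevel=2)
        pixels = pixels.astype(np.uint16) * 257
    elif pixels.dtype != np.uint16:
        warnings.warn(
            f"{path}: {pixels.dtype} input linearly rescaled to 16-bit", stacklevel=2
        )
        lo, hi = float(pixels.min()), float(pixels.max())
        span = hi - lo if hi > lo else 1.0
        pixels = np.round((pixels.astype(float) - lo) * (UINT16_MAX / span)).astype(np.uint16)
    return ImageStack(
        pixels=pixels,
        channel_names=list(channel_names),
        pixel_size=float(pixel_size),
        frame_interval=frame_interval,
    )


def write_polylines(annotations: list[PolylineAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        for i, (x, y) in enumerate(ann.vertices):
            rows.append(
                {"filopodium_id": ann.filopodium_id, "vertex_index": i, "x_px": x, "y_px": y}
            )
    pd.DataFrame(rows, columns=["filopodium_id", "vertex_index", "x_px", "y_px"]).to_csv(
        path, index=False
    )


def read_polylines(path: str | Path) -> list[PolylineAnnotation]:
    """Read tip-first polyline annotations; vertex order is validated."""
    df = _read_csv(path, {"filopodium_id", "vertex_index", "x_px", "y_px"})
    out = []
    for fid, sub in df.groupby("filopodium_id", sort=False):
        idx = sub["vertex_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            dup = int(idx[pd.Series(idx).duplicated()][0])
            raise ParseError(
                f"{path}: duplicated vertex_index {dup} for filopodium {fid!r}"
            )
        if not np.array_equal(np.sort(idx), np.arange(len(idx))):
            raise ParseError(
                f"{path}: vertex indices for filopodium {fid!r} are not 0..n-1"
            )
        sub = sub.sort_values("vertex_index")
        out.append(PolylineAnnotation(fid, sub[["x_px", "y_px"]].to_numpy(dtype=float)))
    return out


def write_profiles(records: list[ProfileRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for i, (d, v) in enumerate(zip(rec.arc_positions_um, rec.intensities)):
            rows.append(
                {
                    "filopodium_id": rec.filopodium_id,
                    "channel": rec.channel,
                    "sample_index": i,
                    "distance_um": d,
                    "intensity": v,
                    "pixel_size_um": rec.pixel_size,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "filopodium_id", "channel", "sample_index",
            "distance_um", "intensity", "pixel_size_um",
        ],
    ).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[ProfileRecord]:
    df = _read_csv(
        path,
        {"filopodium_id", "channel", "sample_index", "distance_um", "intensity", "pixel_size_um"},
    )
    out = []
    for (fid, ch), sub in df.groupby(["filopodium_id", "channel"], sort=False):
        idx = sub["sample_index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(idx))):
            raise ParseError(
                f"{path}: sample indices for ({fid!r}, {ch!r}) are not 0..n-1"
            )
        sub = sub.sort_values("sample_index")
        out.append(
            ProfileRecord(
                filopodium_id=fid,
                channel=ch,
                intensities=sub["intensity"].to_numpy(dtype=float),
                arc_positions_um=sub["distance_um"].to_numpy(dtype=float),
                pixel_size=float(sub["pixel_size_um"].iloc[0]),
            )
        )
    return out


def write_titration(titration: Titration, path: str | Path) -> None:
    pd.DataFrame(
        {"l0_molar": titration.l0, "signal": titration.signal, "a0_molar": titration.a0}
    ).to_csv(path, index=False)


def read_titration(path: str | Path, a0: float | None = None) -> Titration:
    df = _read_csv(path, {"l0_molar", "signal"})
    if a0 is None:
        if "a0_molar" not in df.columns:
            raise CalibrationError(f"{path}: no a0_molar column; pass a0 explicitly")
        a0_vals = df["a0_molar"].unique()
        if len(a0_vals) != 1:
            raise ParseError(f"{path}: a0_molar is not constant")
        a0 = float(a0_vals[0])
    return Titration(a0=a0, l0=df["l0_molar"].to_numpy(float), signal=df["signal"].to_numpy(float))


def write_gold_particles(sets: list[GoldParticleSet], path: str | Path) -> None:
    rows = [
        {"label": s.label, "distance_nm": d} for s in sets for d in s.distances
    ]
    pd.DataFrame(rows, columns=["label", "distance_nm"]).to_csv(path, index=False)


def read_gold_particles(path: str | Path) -> list[GoldParticleSet]:
    df = _read_csv(path, {"label", "distance_nm"})
    return [
        GoldParticleSet(label=str(label), distances=sub["distance_nm"].to_numpy(float))
        for label, sub in df.groupby("label", sort=False)
    ]


def write_flow(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_flow(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"cell_id", "stain", "intensity"})


def write_ct(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_ct(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"gene", "sample", "ct"})


def write_spots(detections: pd.DataFrame, path: str | Path) -> None:
    detections.to_csv(path, index=False)


def read_spots(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, {"frame", "x_um", "y_um"})


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
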