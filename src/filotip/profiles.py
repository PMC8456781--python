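"""Image normalization, tip-to-base profile extraction and spot counting.

Profiles are sampled along manually-drawn (or synthetic) polylines that run
from the filopodium tip to its base at the lamellipodium edge.  Images are
first rescaled so the brightest cellular structure maps to 65535 and the
background mode to 0, which makes the downstream absolute positivity
threshold (5000 ADU) meaningful across acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import local_maxima, reconstruction
from skimage.restoration import rolling_ball

from ._util import as_1d_float
from .errors import ArgumentError, ConstantImageError, EmptyMaskError

UINT16_MAX = 65535


@dataclass
class ProfileRecord:
    """One tip-to-base intensity trace for one filopodium and channel."""

    filopodium_id: str | int
    channel: str
    intensities: np.ndarray      # ADU, tip first
    arc_positions_um: np.ndarray  # distance from tip, strictly increasing from 0
    pixel_size: float            # um / pixel

    def __post_init__(self) -> None:
        self.intensities = as_1d_float(self.intensities, "intensities", min_len=2)
        self.arc_positions_um = as_1d_float(
            self.arc_positions_um, "arc_positions_um", min_len=2
        )
        if self.intensities.size != self.arc_positions_um.size:
            raise ArgumentError("intensities and arc_positions_um must match")
        if self.arc_positions_um[0] != 0 or np.any(np.diff(self.arc_positions_um) <= 0):
            raise ArgumentError("arc positions must increase strictly from 0")

    @property
    def length_um(self) -> float:
        return float(self.arc_positions_um[-1])


def normalize_image(image: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Rescale so the in-mask maximum maps to 65535 and background to 0.

    The background floor is the modal pixel value outside the mask (the mode
    is robust to the dim tail of cellular signal).  Output is uint16, values
    clipped to [0, 65535].
    """
    image = np.asarray(image)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.shape:
        raise ArgumentError("mask shape must match image shape")
    if not cell_mask.any():
        raise EmptyMaskError("cell mask is empty")
    if float(image.max()) == float(image.min()):
        raise ConstantImageError("constant image: normalization scale undefined")
    outside = image[~cell_mask]
    if outside.size:
        counts = np.bincount(np.round(outside.astype(float)).astype(np.int64).clip(0, UINT16_MAX))
        background = float(np.argmax(counts))
    else:
        background = 0.0
    peak = float(image[cell_mask].max())
    if peak <= background:
        raise ConstantImageError(
            f"in-mask maximum ({peak}) does not exceed background ({background})"
        )
    scaled = (image.astype(float) - background) * (UINT16_MAX / (peak - background))
    return np.clip(np.round(scaled), 0, UINT16_MAX).astype(np.uint16)


def _arc_points(polyline_xy: np.ndarray, spacing_px: float = 1.0):
    """Resample a polyline at ~1-px arc spacing; returns (points, arcs, n)."""
    verts = np.asarray(polyline_xy, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 2:
        raise ArgumentError("polyline must be an (n>=2, 2) array of x,y pixels")
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ArgumentError("consecutive polyline vertices must be distinct")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total < 2.0:
        raise ArgumentError(f"polyline arc length {total:.2f}px is shorter than 2px")
    n = max(2, int(round(total / spacing_px)) + 1)
    arcs = np.linspace(0.0, total, n)
    xs = np.interp(arcs, cum, verts[:, 0])
    ys = np.interp(arcs, cum, verts[:, 1])
    return np.column_stack([xs, ys]), arcs, total


def extract_profile(
    image: np.ndarray,
    polyline_xy: np.ndarray,
    pixel_size: float,
    width: int = 1,
    filopodium_id: str | int = 0,
    channel: str = "",
) -> ProfileRecord:
    """Sample a tip-first line intensity profile by bilinear interpolation.

    Samples are taken at ~1-pixel arc spacing starting at the tip vertex.
    ``width > 1`` averages ``width`` parallel samples offset perpendicular to
    the local tangent (1-pixel steps centred on the line).
    """
    if pixel_size <= 0:
        raise ArgumentError("pixel_size must be > 0")
    if width < 1 or width % 2 == 0:
        raise ArgumentError("width must be an odd positive pixel count")
    pts, arcs, _ = _arc_points(polyline_xy)
    img = np.asarray(image, dtype=float)

    tangents = np.gradient(pts, axis=0)
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    tangents /= norms[:, None]
    normal = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    offsets = np.arange(width) - (width - 1) / 2.0
    acc = np.zeros(len(pts))
    for off in offsets:
        sample = pts + off * normal
        acc += ndimage.map_coordinates(
            img, [sample[:, 1], sample[:, 0]], order=1, mode="nearest"
        )
    values = acc / width
    return ProfileRecord(
        filopodium_id=filopodium_id,
        channel=channel,
        intensities=np.clip(values, 0, UINT16_MAX),
        arc_positions_um=arcs * pixel_size,
        pixel_size=pixel_size,
    )


def find_maxima(image: np.ndarray, prominence: float) -> np.ndarray:
    """Local maxima with prominence >= threshold (ImageJ Find-Maxima style).

    A maximum counts when the descent to the saddle separating it from any
    higher region is at least ``prominence``.  Implemented by greyscale
    reconstruction of ``image - h`` under ``image`` (h-maxima); two peaks
    whose joining saddle dips by less than the prominence merge into one.
    For integer images ``h = prominence - 0.5`` realizes the inclusive
    ">= prominence" rule exactly.

    Returns an (n, 2) array of (row, col) coordinates, one per maximum
    (the brightest pixel of each merged plateau).
    """
    if prominence <= 0:
        raise ArgumentError("prominence must be > 0")
    img = np.asarray(image, dtype=float)
    h = prominence - 0.5 if np.issubdtype(np.asarray(image).dtype, np.integer) else prominence
    rec = reconstruction(img - h, img, method="dilation")
    peaks = local_maxima(rec, connectivity=2)
    labels = cc_label(peaks, connectivity=2)
    coords = []
    for region in range(1, labels.max() + 1):
        rr, cc = np.nonzero(labels == region)
        best = np.argmax(img[rr, cc])
        coords.append((rr[best], cc[best]))
    return np.array(coords, dtype=int).reshape(-1, 2)


def cell_mask_from_factin(
    factin: np.ndarray,
    threshold: float | None = None,
    keep_largest: int = 1,
) -> np.ndarray:
    """Cell-body mask from an F-actin staining.

    Otsu threshold by default (overridable), hole filling, then the largest
    connected component(s) are kept.
    """
    img = np.asarray(factin, dtype=float)
    thr = float(threshold) if threshold is not None else float(threshold_otsu(img))
    mask = img > thr
    if not mask.any():
        raise EmptyMaskError("F-actin mask is empty: no cell detected")
    mask = ndimage.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.argsort(sizes)[::-1][: max(1, keep_largest)] + 1
    return np.isin(labels, keep)


def count_myo10_spots(
    myo10_image: np.ndarray,
    factin_image: np.ndarray,
    prominence: float,
    mask_threshold: float | None = None,
    background_radius: float | None = 50.0,
) -> int:
    """Count extracellular MYO10 puncta in a screen field of view.

    Spots are local maxima of the (optionally rolling-ball background
    subtracted) MYO10 channel with prominence >= ``prominence``; maxima that
    fall inside the F-actin-derived cell mask (intracellular MYO10 pools)
    are excluded, so the count reflects filopodia-tip puncta.
    """
    myo10 = np.asarray(myo10_image)
    if myo10.shape != np.asarray(factin_image).shape:
        raise ArgumentError("MYO10 and F-actin images must share a shape")
    mask = cell_mask_from_factin(factin_image, threshold=mask_threshold)
    work = myo10.astype(float)
    if background_radius:
        work = work - rolling_ball(work, radius=background_radius)
        work = np.clip(work, 0, None)
        if np.issubdtype(myo10.dtype, np.integer):
            work = np.round(work)
            h_img = work.astype(np.int64)
        else:
            h_img = work
    else:
        h_img = myo10
    coords = find_maxima(h_img, prominence)
    if coords.size == 0:
        return 0
    outside = ~mask[coords[:, 0], coords[:, 1]]
    return int(np.count_nonzero(outside))
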