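"""Frame segmentation: thresholding, morphological cleanup and per-seed regions.

A *frame* is an ``(H, W, 3)`` uint8 RGB array of seeds on a dark background.
Segmentation follows the classical recipe: global threshold on the mean-channel
gray image, a morphological opening to drop specks, hole filling, and finally
connected-component labelling.  Each component becomes a :class:`SeedRegion`
with a tight binary mask, a masked color crop, and a traced boundary contour.

Coordinates are (row, col), 0-based; bounding boxes are half-open.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

logger = logging.getLogger(__name__)

# clockwise Moore neighbourhood starting north
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass
class SeedRegion:
    """One segmented seed.

    Attributes
    ----------
    mask : (h, w) bool array — tight crop of the seed's binary mask.
    subimage : (h, w, 3) uint8 array — color crop with background zeroed.
    contour : (n, 2) int array — boundary pixel coordinates in crop-local
        (row, col) order, traced clockwise by Moore boundary following; the
        first point is 8-adjacent to the last (closed).
    centroid : (row, col) floats in frame coordinates.
    bbox : (row0, col0, row1, col1) half-open, frame coordinates.
    area_px : number of mask-true pixels.
    """

    mask: np.ndarray
    subimage: np.ndarray
    contour: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    area_px: int
    region_id: int = 0

    def __post_init__(self) -> None:
        if self.area_px != int(self.mask.sum()) or self.area_px <= 0:
            raise ValueError("area_px must equal the number of true mask pixels (> 0)")
        if np.any(self.subimage[~self.mask]):
            raise ValueError("subimage must be zero outside the mask")

    @property
    def gray(self) -> np.ndarray:
        """Mean-channel gray crop as float64 (zero outside the mask)."""
        return self.subimage.mean(axis=2)


def _validate_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be an (H, W, 3) RGB array")
    if frame.shape[0] < 1 or frame.shape[1] < 1 or frame.size == 0:
        raise ValueError("frame is empty")
    return frame


def read_frame(path: str | Path) -> np.ndarray:
    """Read a PNG/BMP image as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_frame(path: str | Path, frame: np.ndarray) -> None:
    Image.fromarray(np.asarray(frame, dtype=np.uint8)).save(path)


def binarize(
    frame: np.ndarray,
    threshold_mode: str = "otsu",
    fixed_t: float | None = None,
    dark_background: bool = True,
) -> np.ndarray:
    """Threshold the mean-channel gray image into a foreground mask.

    Foreground is where gray exceeds the threshold when ``dark_background``
    (seeds brighter than the field); the polarity flips otherwise.
    """
    frame = _validate_frame(frame)
    gray = frame.astype(np.float64).mean(axis=2)
    if threshold_mode == "fixed":
        if fixed_t is None:
            raise ValueError("fixed_t is required when threshold_mode='fixed'")
        t = float(fixed_t)
    elif threshold_mode == "otsu":
        if fixed_t is not None:
            raise ValueError("fixed_t is only valid with threshold_mode='fixed'")
        if np.ptp(gray) == 0:
            warnings.warn("constant frame: Otsu threshold undefined, returning empty mask")
            return np.zeros(gray.shape, dtype=bool)
        t = float(threshold_otsu(gray))
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return gray > t if dark_background else gray < t


def morph_clean(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a disk element.

    Removes foreground components smaller than the structuring element.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    selem = disk(radius)
    # border_value=1 for the erosion so a solid field passes through unchanged
    eroded = ndi.binary_erosion(np.asarray(mask, dtype=bool), structure=selem, border_value=1)
    return ndi.binary_dilation(eroded, structure=selem, border_value=0)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def apply_mask(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """AND the color frame with the binary mask (background zeroed)."""
    frame = _validate_frame(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match frame {frame.shape[:2]}")
    return np.where(mask[..., None], frame, 0).astype(frame.dtype)


def moore_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the largest-first foreground component.

    Clockwise Moore boundary following starting at the row-major-first
    foreground pixel.  Returns (n, 2) int coordinates; a single isolated pixel
    yields a length-1 contour.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    if rows.size == 0:
        raise ValueError("cannot trace an empty mask")
    start = (int(rows[0]), int(cols[0]))
    contour = [start]
    # entered while scanning row-major, i.e. from the left neighbour
    state = (start, (start[0], start[1] - 1))
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    while state not in seen:
        seen.add(state)
        cur, prev = state
        i = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            dr, dc = _MOORE[(i + k) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                nxt = cand
                pr, pc = _MOORE[(i + k - 1) % 8]
                new_prev = (cur[0] + pr, cur[1] + pc)
                break
        if nxt is None:  # isolated pixel
            break
        contour.append(nxt)
        state = (nxt, new_prev)
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.array(contour, dtype=np.int64) - 1


def extract_regions(frame: np.ndarray, mask: np.ndarray, min_area: int = 50) -> list[SeedRegion]:
    """Split the mask into 8-connected components of area >= ``min_area``.

    Regions are ordered row-major by centroid.  Each region's contour is
    traced with Moore boundary following on its tight mask crop.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    frame = _validate_frame(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape[:2]:
        raise ValueError("mask shape does not match frame")
    labels = cc_label(mask, connectivity=2)
    regions: list[SeedRegion] = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(comp)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        crop_mask = comp[r0:r1, c0:c1]
        sub = np.where(crop_mask[..., None], frame[r0:r1, c0:c1], 0).astype(frame.dtype)
        centroid = (float(rows.mean()), float(cols.mean()))
        regions.append(
            SeedRegion(
                mask=crop_mask,
                subimage=sub,
                contour=moore_contour(crop_mask),
                centroid=centroid,
                bbox=(r0, c0, r1, c1),
                area_px=area,
            )
        )
    regions.sort(key=lambda r: (r.centroid[0], r.centroid[1]))
    for i, reg in enumerate(regions):
        reg.region_id = i
    return regions


def segment_frame(
    frame: np.ndarray,
    threshold_mode: str = "otsu",
    fixed_t: float | None = None,
    morph_radius: int = 2,
    min_area: int = 50,
    dark_background: bool = True,
) -> list[SeedRegion]:
    """Full segmentation chain: binarize, open, fill holes, extract regions."""
    mask = binarize(frame, threshold_mode, fixed_t, dark_background)
    mask = fill_holes(morph_clean(mask, morph_radius))
    return extract_regions(frame, mask, min_area)


def save_regions(regions: list[SeedRegion], out_dir: str | Path) -> Path:
    """Write per-region PNG crops plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for reg in regions:
        name = f"region_{reg.region_id:03d}.png"
        write_frame(out / name, reg.subimage)
        manifest.append(
            {
                "id": reg.region_id,
                "file": name,
                "bbox": list(reg.bbox),
                "centroid": list(reg.centroid),
                "area_px": reg.area_px,
            }
        )
    path = out / "regions.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
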