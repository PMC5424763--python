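"""Texture features: GLCM statistics and the local similarity pattern (LSP).

GLCM
    The gray-level co-occurrence matrix P(i, j | d, theta) is the normalized
    frequency of ordered gray-level pairs at displacement d along orientation
    theta in {0, 45, 90, 135} degrees.  Both pixels of a pair must lie inside
    the seed mask.  Gray values are quantized into equal-width bins over
    [0, 255].  Four statistics are read off each matrix — angular second
    moment, entropy (-sum p ln p), contrast, homogeneity — and averaged over
    the four orientations, which makes them approximately rotation invariant.

LSP
    A rotation-invariant local operator: for every interior seed pixel the
    fraction of its 8 neighbours whose gray level is within ``similarity_t``
    of the center.  Its mask-wide mean ("LSP gray average") drops in the
    presence of spots or local defects.  The companion scale statistic is a
    Tamura-style coarseness: per pixel, the window size 2^k (k = 1..kmax)
    maximizing the directional average-difference of window means, averaged
    over the mask; blockier textures score higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, uniform_filter

ORIENTATIONS = (0, 45, 90, 135)

# (row, col) displacement per orientation for the *second* pixel of a pair,
# with rows increasing downward (45 degrees points up-right).
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMatrix:
    """A normalized co-occurrence matrix for one (distance, orientation)."""

    p: np.ndarray
    levels: int
    d: int
    theta: int

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.p.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be (levels, levels)")
        if not np.isclose(self.p.sum(), 1.0):
            raise ValueError("matrix must be normalized to sum 1")


@dataclass
class TextureFeatures:
    """Six texture descriptors (CSV columns tex_07 ... tex_12)."""

    lsp_gray_average: float
    entropy: float
    asm: float
    contrast: float
    homogeneity: float
    lsp_coarseness: float

    _ORDER = ("lsp_gray_average", "entropy", "asm", "contrast", "homogeneity", "lsp_coarseness")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {f"tex_{i + 7:02d}": float(getattr(self, k)) for i, k in enumerate(self._ORDER)}


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 255] gray values into ``levels`` bins."""
    q = (np.asarray(gray, dtype=np.float64) * levels / 256.0).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def compute_glcm(gray: np.ndarray, mask: np.ndarray | None, d: int = 1,
                 theta: int = 0, levels: int = 16) -> GLCMatrix:
    """Count ordered gray-level pairs at displacement (d, theta) inside the mask."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {ORIENTATIONS}")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    gray = np.asarray(gray)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    q = quantize(gray, levels)
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    if r0s >= r0e or c0s >= c0e:
        raise ValueError("no valid pixel pair at this displacement")
    src = q[r0s:r0e, c0s:c0e]
    dst = q[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid pixel pair inside the mask")
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (src[valid], dst[valid]), 1.0)
    return GLCMatrix(p=counts / n, levels=levels, d=d, theta=theta)


def glcm_features(glcm: GLCMatrix) -> tuple[float, float, float, float]:
    """(ASM, entropy, contrast, homogeneity) of one normalized GLCM."""
    p = glcm.p
    asm = float((p ** 2).sum())
    pos = p[p > 0]
    ent = float(-(pos * np.log(pos)).sum())
    i, j = np.meshgrid(np.arange(glcm.levels), np.arange(glcm.levels), indexing="ij")
    diff2 = (i - j) ** 2
    con = float((diff2 * p).sum())
    hom = float((p / (1.0 + diff2)).sum())
    return asm, ent, con, hom


def aggregate_orientations(values) -> float:
    """Arithmetic mean of the four per-orientation feature values."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (4,):
        raise ValueError("exactly four per-orientation values are required")
    return float(values.mean())


def lsp_map(gray: np.ndarray, mask: np.ndarray, similarity_t: float = 10.0
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel fraction of similar 8-neighbours.

    Returns ``(values, eligible)``: ``values[r, c]`` is the fraction of the 8
    neighbours of (r, c) whose absolute gray difference from the center is at
    most ``similarity_t``; ``eligible`` marks mask-true pixels whose 8
    neighbours are all mask-true (values elsewhere are NaN).
    """
    if similarity_t < 0:
        raise ValueError("similarity_t must be >= 0")
    gray = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    eligible = binary_erosion(mask, np.ones((3, 3)), border_value=0)
    if not eligible.any():
        raise ValueError("no pixel has all 8 neighbours inside the mask")
    counts = np.zeros(gray.shape, dtype=np.float64)
    padded = np.pad(gray, 1, mode="edge")
    h, w = gray.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            neigh = padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
            counts += (np.abs(neigh - gray) <= similarity_t)
    values = np.where(eligible, counts / 8.0, np.nan)
    return values, eligible


def _tamura_coarseness(gray: np.ndarray, mask: np.ndarray, kmax: int) -> float:
    """Tamura coarseness restricted to mask pixels with full in-bounds windows."""
    h, w = gray.shape
    # shrink kmax until at least one pixel has margin 2^k on every side
    while kmax >= 1:
        margin = 2 ** kmax
        if h > 2 * margin and w > 2 * margin:
            inner = mask[margin:h - margin, margin:w - margin]
            if inner.any():
                break
        kmax -= 1
    else:
        raise ValueError("region smaller than the smallest coarseness window")
    best_e = np.full(gray.shape, -1.0)
    best_s = np.zeros(gray.shape)
    for k in range(1, kmax + 1):
        size = 2 ** k
        half = 2 ** (k - 1)
        avg = uniform_filter(gray, size=size, mode="nearest")
        eh = np.abs(np.roll(avg, -half, axis=1) - np.roll(avg, half, axis=1))
        ev = np.abs(np.roll(avg, -half, axis=0) - np.roll(avg, half, axis=0))
        e = np.maximum(eh, ev)
        take = e > best_e
        best_e = np.where(take, e, best_e)
        best_s = np.where(take, float(size), best_s)
    margin = 2 ** kmax
    sel = np.zeros(gray.shape, dtype=bool)
    sel[margin:h - margin, margin:w - margin] = mask[margin:h - margin, margin:w - margin]
    return float(best_s[sel].mean())


def lsp_features(gray: np.ndarray, mask: np.ndarray, similarity_t: float = 10.0,
                 coarseness_kmax: int = 4) -> tuple[float, float]:
    """(LSP gray average, LSP coarseness) over the masked region."""
    values, eligible = lsp_map(gray, mask, similarity_t)
    lsp_avg = float(values[eligible].mean())
    coarseness = _tamura_coarseness(np.asarray(gray, dtype=np.float64),
                                    np.asarray(mask, dtype=bool), coarseness_kmax)
    return lsp_avg, coarseness


def texture_features(gray: np.ndarray, mask: np.ndarray, d: int = 1,
                     levels: int = 16, similarity_t: float = 10.0,
                     coarseness_kmax: int = 4) -> TextureFeatures:
    """All six texture descriptors of a masked gray sub-image."""
    per_orient = [glcm_features(compute_glcm(gray, mask, d, th, levels))
                  for th in ORIENTATIONS]
    asm, ent, con, hom = (aggregate_orientations([po[i] for po in per_orient])
                          for i in range(4))
    lsp_avg, coarse = lsp_features(gray, mask, similarity_t, coarseness_kmax)
    return TextureFeatures(
        lsp_gray_average=lsp_avg,
        entropy=ent,
        asm=asm,
        contrast=con,
        homogeneity=hom,
        lsp_coarseness=coarse,
    )
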