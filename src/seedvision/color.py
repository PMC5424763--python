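"""Color features: channel means over the masked seed pixels.

Six features are reported per seed: the mean R, G and B values, the mean hue
and saturation of the geometric HSI color model, and the mean gray level
(R+G+B)/3.  Hue is reported on [0, 1] as degrees/360 and, by default, is
averaged arithmetically on that scale; note this biases seeds whose hues
straddle the 0/360-degree wraparound, so a circular mean is available via
``circular_hue=True``.  Intensity I equals the mean gray level under this
HSI definition, so the gray feature doubles as ``i_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from seedvision.imaging import SeedRegion


@dataclass
class ColorFeatures:
    """Six color descriptors (CSV columns color_01 ... color_06)."""

    b_mean: float
    g_mean: float
    r_mean: float
    h_mean: float  # degrees / 360, in [0, 1]
    s_mean: float  # in [0, 1]
    gray_mean: float  # in [0, 255]

    _ORDER = ("b_mean", "g_mean", "r_mean", "h_mean", "s_mean", "gray_mean")

    @property
    def i_mean(self) -> float:
        """Alias: HSI intensity mean is numerically the gray mean."""
        return self.gray_mean

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=np.float64)

    def to_dict(self) -> dict[str, float]:
        return {f"color_{i + 1:02d}": float(getattr(self, k)) for i, k in enumerate(self._ORDER)}


def rgb_to_hsi(r, g, b):
    """Geometric RGB -> HSI conversion.

    Parameters are intensities in [0, 255]; scalars or arrays. Returns
    ``(h, s, i)`` with hue in degrees [0, 360), saturation in [0, 1] and
    intensity in [0, 255].  Achromatic pixels (s == 0) get hue 0.
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    total = r + g + b
    i = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cosang = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0), -1.0, 1.0)
        theta = np.degrees(np.arccos(cosang))
    h = np.where(b > g, 360.0 - theta, theta)
    h = np.where(s == 0, 0.0, h)
    if h.ndim == 0:
        return float(h), float(s), float(i)
    return h, s, i


def color_features(region: SeedRegion, circular_hue: bool = False) -> ColorFeatures:
    """Channel means over the mask-true pixels of a seed region."""
    mask = region.mask
    if not mask.any():
        raise ValueError("empty mask: no pixels to average")
    px = region.subimage[mask].astype(np.float64)  # (n, 3) RGB
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    h, s, _ = rgb_to_hsi(r, g, b)
    if circular_hue:
        rad = np.deg2rad(h)
        h_mean = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0) / 360.0
    else:
        h_mean = float(h.mean()) / 360.0
    return ColorFeatures(
        b_mean=float(b.mean()),
        g_mean=float(g.mean()),
        r_mean=float(r.mean()),
        h_mean=h_mean,
        s_mean=float(s.mean()),
        gray_mean=float((r.mean() + g.mean() + b.mean()) / 3.0),
    )
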