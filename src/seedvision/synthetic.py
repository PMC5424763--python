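"""Synthetic seed frames with exact ground truth.

Renders grids of seed-like blobs on a dark field so every pipeline stage can
be exercised against known answers.  Each seed has a shape class (circular,
oval, triangular, elongated, irregular), a surface color class (reddish-brown
or black for sound seeds; gray or white for stale ones), a surface-spot
density and a roughness (additive gray noise).  The generator's ground-truth
quality rule mirrors those phenotypes:

    good  <=>  shape in {circular, oval}
               and color in {reddish_brown, black}
               and spot_density < 0.02

Seeds are rendered as anti-aliased filled shapes (3x3 supersampled coverage)
with a radial shading gradient, Poisson-placed dark spots and additive
Gaussian roughness, entirely deterministic in the plan's seed.  The default
frame is 400 x 400 px with a 3 x 7 grid of 21 seeds, a desk-scale version of
a detection-region snapshot; full 1600 x 1200 frames are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seedvision.features import extract_features
from seedvision.imaging import segment_frame

SHAPE_CLASSES = ("circular", "oval", "triangular", "elongated", "irregular")
COLOR_CLASSES = ("reddish_brown", "black", "gray", "white")
GOOD_SHAPES = frozenset({"circular", "oval"})
GOOD_COLORS = frozenset({"reddish_brown", "black"})
SPOT_THRESHOLD = 0.02

_BASE_COLORS = {
    "reddish_brown": (165.0, 85.0, 50.0),
    "black": (100.0, 90.0, 80.0),
    "gray": (150.0, 150.0, 148.0),
    "white": (215.0, 212.0, 205.0),
}


@dataclass
class SeedSpec:
    """Ground-truth description of one rendered seed."""

    shape_class: str
    color_class: str
    spot_density: float
    roughness: float
    size_px: float
    center: tuple[float, float]
    orientation: float = 0.0
    color_jitter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape_params: tuple = ()

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if self.color_class not in COLOR_CLASSES:
            raise ValueError(f"unknown color class {self.color_class!r}")
        if not 0.0 <= self.spot_density <= 0.2:
            raise ValueError("spot_density must be in [0, 0.2]")

    @property
    def shape_ok(self) -> bool:
        return self.shape_class in GOOD_SHAPES

    @property
    def colortex_ok(self) -> bool:
        return self.color_class in GOOD_COLORS and self.spot_density < SPOT_THRESHOLD

    @property
    def label(self) -> str:
        return "good" if self.shape_ok and self.colortex_ok else "ng"


@dataclass
class FramePlan:
    """Layout of one synthetic frame."""

    specs: list[SeedSpec]
    frame_shape: tuple[int, int] = (400, 400)
    grid: tuple[int, int] = (3, 7)
    background: float = 10.0
    rng_seed: int = 0


@dataclass
class FrameTruth:
    """Per-seed ground truth returned next to a rendered frame."""

    masks: list[np.ndarray]
    specs: list[SeedSpec]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [s.label for s in self.specs]

    @property
    def centroids(self) -> list[tuple[float, float]]:
        return [s.center for s in self.specs]


def _radial_profile(spec: SeedSpec, theta: np.ndarray) -> np.ndarray:
    """Polar radius r(theta) of the seed outline, relative to size_px."""
    r0 = spec.size_px
    if spec.shape_class == "triangular":
        amp = spec.shape_params[0] if spec.shape_params else 0.22
        return r0 * (1.0 + amp * np.cos(3.0 * (theta - spec.orientation)))
    if spec.shape_class == "irregular":
        out = np.full_like(theta, 1.0)
        for k, (a, phi) in enumerate(spec.shape_params, start=2):
            out = out + a * np.cos(k * theta + phi)
        return r0 * out
    raise ValueError("radial profile only defined for triangular/irregular")


_ASPECTS = {"circular": (1.0, 1.0), "oval": (1.25, 0.8), "elongated": (1.7, 0.55)}


def _coverage(spec: SeedSpec, rows: np.ndarray, cols: np.ndarray, ss: int = 3) -> np.ndarray:
    """Anti-aliased membership of grid pixels, by ss x ss supersampling."""
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    # (H, W, ss, ss) sample coordinates relative to the seed center
    dy = rows[:, :, None, None] + oy[None, None] - spec.center[0]
    dx = cols[:, :, None, None] + ox[None, None] - spec.center[1]
    if spec.shape_class in _ASPECTS:
        fa, fb = _ASPECTS[spec.shape_class]
        a, b = spec.size_px * fa, spec.size_px * fb
        co, si = np.cos(spec.orientation), np.sin(spec.orientation)
        u = dx * co + dy * si
        v = -dx * si + dy * co
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:
        rho = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        inside = rho <= _radial_profile(spec, theta)
    return inside.mean(axis=(2, 3))


def render_seed(spec: SeedSpec, frame: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Composite one seed into ``frame`` (float RGB); returns its truth mask."""
    h, w = frame.shape[:2]
    extent = int(np.ceil(spec.size_px * 2.0)) + 3
    r0 = max(int(spec.center[0]) - extent, 0)
    r1 = min(int(spec.center[0]) + extent + 1, h)
    c0 = max(int(spec.center[1]) - extent, 0)
    c1 = min(int(spec.center[1]) + extent + 1, w)
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    alpha = _coverage(spec, rows, cols)

    base = np.array(_BASE_COLORS[spec.color_class]) + np.array(spec.color_jitter)
    rho = np.hypot(rows - spec.center[0], cols - spec.center[1]) / max(spec.size_px, 1.0)
    shading = 1.0 - 0.12 * np.clip(rho, 0.0, 1.3) ** 2
    color = base[None, None, :] * shading[:, :, None]

    solid = alpha > 0.5
    area = float(solid.sum())
    n_spots = rng.poisson(spec.spot_density * area)
    if n_spots:
        ys, xs = np.nonzero(solid)
        for _ in range(int(n_spots)):
            j = rng.integers(len(ys))
            sy, sx = ys[j], xs[j]
            sr = rng.uniform(0.8, 1.6)
            d2 = (rows - (r0 + sy)) ** 2 + (cols - (c0 + sx)) ** 2
            spot = d2 <= sr ** 2
            # spots darken the surface but stay well above the background,
            # so they read as surface defects rather than holes
            color[spot] = np.clip(color[spot] * 0.65, 70.0, None)

    if spec.roughness > 0:
        color += rng.normal(0.0, spec.roughness, size=color.shape)

    patch = frame[r0:r1, c0:c1]
    frame[r0:r1, c0:c1] = patch * (1 - alpha[..., None]) + color * alpha[..., None]
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r1, c0:c1] = solid
    return mask


def make_frame(plan: FramePlan) -> tuple[np.ndarray, FrameTruth]:
    """Render a frame; returns (uint8 RGB frame, per-seed ground truth)."""
    h, w = plan.frame_shape
    rng = np.random.default_rng(plan.rng_seed)
    frame = np.full((h, w, 3), float(plan.background))
    frame += rng.normal(0.0, 1.0, size=frame.shape)
    masks = []
    occupied = np.zeros((h, w), dtype=bool)
    for spec in plan.specs:
        mask = render_seed(spec, frame, rng)
        if (mask & occupied).any():
            raise ValueError(f"seed at {spec.center} overlaps a previous seed")
        occupied |= mask
        masks.append(mask)
    return np.clip(frame, 0, 255).astype(np.uint8), FrameTruth(masks=masks, specs=list(plan.specs))


def sample_spec(rng: np.random.Generator, label: str, center: tuple[float, float],
                size_range: tuple[float, float] = (11.0, 14.0)) -> SeedSpec:
    """Draw one seed specification with the requested ground-truth label.

    NG seeds violate one primary aspect (shape, color or spots, chosen
    uniformly) and each remaining aspect independently with probability 1/4,
    so single- and multi-fault rejects both occur.
    """
    size = float(rng.uniform(*size_range))
    if label == "good":
        bad_shape = bad_color = bad_spots = False
    elif label == "ng":
        which = rng.integers(3)
        extra = rng.random(3) < 0.25
        bad_shape = which == 0 or extra[0]
        bad_color = which == 1 or extra[1]
        bad_spots = which == 2 or extra[2]
    else:
        raise ValueError(f"unknown label {label!r}")

    if bad_shape:
        shape = str(rng.choice(["triangular", "elongated", "irregular"]))
    else:
        shape = str(rng.choice(["circular", "oval"]))
    color = str(rng.choice(["gray", "white"] if bad_color else ["reddish_brown", "black"]))
    if bad_spots:
        spots = float(rng.uniform(0.04, 0.10))
        rough = float(rng.uniform(5.0, 8.0))
    else:
        spots = float(rng.uniform(0.0, 0.015))
        rough = float(rng.uniform(2.0, 4.0))

    params: tuple = ()
    if shape == "triangular":
        params = (float(rng.uniform(0.18, 0.26)),)
    elif shape == "irregular":
        params = tuple((float(rng.uniform(0.07, 0.15)), float(rng.uniform(0, 2 * np.pi)))
                       for _ in range(2, 6))
    return SeedSpec(
        shape_class=shape, color_class=color, spot_density=spots, roughness=rough,
        size_px=size, center=center, orientation=float(rng.uniform(0, np.pi)),
        color_jitter=tuple(rng.normal(0.0, 6.0, size=3)), shape_params=params,
    )


def random_plan(labels: list[str], rng_seed: int = 0,
                frame_shape: tuple[int, int] = (400, 400),
                grid: tuple[int, int] = (3, 7), background: float = 10.0) -> FramePlan:
    """Place one seed per grid cell (row-major) with a small center jitter."""
    n_rows, n_cols = grid
    if len(labels) > n_rows * n_cols:
        raise ValueError("more labels than grid cells")
    rng = np.random.default_rng(rng_seed)
    ch = frame_shape[0] / n_rows
    cw = frame_shape[1] / n_cols
    specs = []
    for i, lab in enumerate(labels):
        gr, gc = divmod(i, n_cols)
        jitter = rng.uniform(-3.0, 3.0, size=2)
        center = ((gr + 0.5) * ch + jitter[0], (gc + 0.5) * cw + jitter[1])
        specs.append(sample_spec(rng, lab, center))
    return FramePlan(specs=specs, frame_shape=frame_shape, grid=grid,
                     background=background, rng_seed=rng_seed)


def _match_regions(regions, truth: FrameTruth, max_dist: float = 10.0):
    """One-to-one pairing of segmented regions with ground-truth seeds.

    Each truth seed claims its nearest unclaimed region (largest area wins a
    tie) within ``max_dist`` of its center; unmatched regions or seeds are
    dropped with a warning.
    """
    pairs = []
    used = set()
    for j, spec in enumerate(truth.specs):
        best = None
        for i, reg in enumerate(regions):
            if i in used:
                continue
            d2 = (reg.centroid[0] - spec.center[0]) ** 2 + (reg.centroid[1] - spec.center[1]) ** 2
            if d2 > max_dist ** 2:
                continue
            key = (d2, -reg.area_px)
            if best is None or key < best[0]:
                best = (key, i)
        if best is None:
            warnings.warn(f"seed at {spec.center} was not recovered by segmentation")
            continue
        used.add(best[1])
        pairs.append((regions[best[1]], spec))
    if len(used) < len(regions):
        warnings.warn(f"{len(regions) - len(used)} segmented region(s) match no seed")
    return pairs


def make_feature_dataset(n_good: int, n_ng: int, rng_seed: int = 0,
                         frame_shape: tuple[int, int] = (400, 400),
                         grid: tuple[int, int] = (3, 7),
                         segment_kwargs: dict | None = None,
                         feature_kwargs: dict | None = None) -> pd.DataFrame:
    """Render seeds, run the real segmentation + feature stack, label the rows.

    Features come from actual rendered images, not from sampled
    distributions.  The returned table has the 27 feature columns plus
    ``label`` and ground-truth metadata columns (``shape_class``,
    ``color_class``, ``spot_density``, ``shape_ok``, ``colortex_ok``).
    """
    if n_good < 1 or n_ng < 1:
        raise ValueError("need at least one seed per class")
    segment_kwargs = segment_kwargs or {}
    feature_kwargs = feature_kwargs or {}
    rng = np.random.default_rng(rng_seed)
    labels = ["good"] * n_good + ["ng"] * n_ng
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    capacity = grid[0] * grid[1]
    rows = []
    for fi in range(0, len(labels), capacity):
        chunk = labels[fi:fi + capacity]
        plan = random_plan(chunk, rng_seed=int(rng.integers(2 ** 31 - 1)),
                           frame_shape=frame_shape, grid=grid)
        frame, truth = make_frame(plan)
        regions = segment_frame(frame, **segment_kwargs)
        for reg, spec in _match_regions(regions, truth):
            row = extract_features(reg, **feature_kwargs)
            row.update(
                label=spec.label, shape_class=spec.shape_class,
                color_class=spec.color_class, spot_density=spec.spot_density,
                shape_ok=spec.shape_ok, colortex_ok=spec.colortex_ok,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def make_labeled_frames(labels_per_frame: list[list[str]], rng_seed: int = 0,
                        frame_shape: tuple[int, int] = (400, 400),
                        grid: tuple[int, int] = (3, 7)):
    """Frames plus run_pipeline-style truth: (frames, [[(centroid, label)]])."""
    rng = np.random.default_rng(rng_seed)
    frames, truths = [], []
    for chunk in labels_per_frame:
        plan = random_plan(chunk, rng_seed=int(rng.integers(2 ** 31 - 1)),
                           frame_shape=frame_shape, grid=grid)
        frame, truth = make_frame(plan)
        frames.append(frame)
        truths.append(list(zip(truth.centroids, truth.labels)))
    return frames, truths
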