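"""Assemble the full 27-feature record of one segmented seed.

Column naming keeps the two selection pools' numbering: shape features are
``shape_01`` ... ``shape_15``; the color-texture pool numbers colors 1-6
(``color_01`` ... ``color_06``) and textures 7-12 (``tex_07`` ... ``tex_12``).
"""

from __future__ import annotations

import pandas as pd

from seedvision.color import color_features
from seedvision.imaging import SeedRegion
from seedvision.shape import shape_features, summarize_geometry
from seedvision.texture import texture_features

SHAPE_COLUMNS = [f"shape_{i:02d}" for i in range(1, 16)]
COLOR_COLUMNS = [f"color_{i:02d}" for i in range(1, 7)]
TEXTURE_COLUMNS = [f"tex_{i:02d}" for i in range(7, 13)]
COLORTEX_COLUMNS = COLOR_COLUMNS + TEXTURE_COLUMNS
ALL_COLUMNS = SHAPE_COLUMNS + COLORTEX_COLUMNS

# pool-number -> column, per net
SHAPE_POOL = {i: f"shape_{i:02d}" for i in range(1, 16)}
COLORTEX_POOL = {**{i: f"color_{i:02d}" for i in range(1, 7)},
                 **{i: f"tex_{i:02d}" for i in range(7, 13)}}


def extract_features(region: SeedRegion, glcm_levels: int = 16, glcm_distance: int = 1,
                     lsp_similarity_t: float = 10.0, coarseness_kmax: int = 4,
                     circular_hue: bool = False) -> dict[str, float]:
    """All 27 features of one region as a column-keyed dict."""
    row: dict[str, float] = {}
    row.update(shape_features(summarize_geometry(region)).to_dict())
    row.update(color_features(region, circular_hue=circular_hue).to_dict())
    row.update(
        texture_features(
            region.gray, region.mask, d=glcm_distance, levels=glcm_levels,
            similarity_t=lsp_similarity_t, coarseness_kmax=coarseness_kmax,
        ).to_dict()
    )
    return row


def features_table(regions: list[SeedRegion], **kwargs) -> pd.DataFrame:
    """Feature rows for a list of regions, indexed by region id."""
    rows = [extract_features(r, **kwargs) for r in regions]
    df = pd.DataFrame(rows, columns=ALL_COLUMNS)
    df.insert(0, "region_id", [r.region_id for r in regions])
    return df
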