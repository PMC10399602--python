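"""Per-image feature extraction: the full ~58-statistic battery.

Combines the chromatic statistics (cone-opponent moments, CIELUV RMS
contrast, hue segments, natural chromatic elongation and ellipse angle)
with the spatial battery (spectral slope, fractal dimensions, lacunarity,
entropy, edge densities, Gabor edge density, edge-orientation entropies,
PHOG measures) into one named row per image.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import chromatic, colorspace, spatial

__all__ = ["image_features", "feature_table", "CHANNEL_NAMES"]

CHANNEL_NAMES = ("lum", "l", "s")


def _channels(field: colorspace.ChromaticField) -> dict[str, np.ndarray]:
    """Spatial-analysis channels; dark pixels take the white-point
    chromaticity so the fields stay finite."""
    wp = field.white
    l = np.where(np.isfinite(field.l), field.l, wp.l0)
    s = np.where(np.isfinite(field.s), field.s, wp.s0)
    return {"lum": field.lum, "l": l, "s": s}


def image_features(
    rgb_linear: np.ndarray,
    rgb_gamma: np.ndarray | None = None,
    wp: colorspace.WhitePoint | None = None,
    seed: int = 0,
    eoe_max_edges: int = 10_000,
) -> dict[str, float]:
    """All chromatic and spatial statistics of one linear-RGB image.

    ``rgb_gamma`` (the gamma-encoded original) feeds the grayscale luma
    statistics; if omitted it is re-encoded from the linear image.
    """
    wp = wp or colorspace.WhitePoint()
    if rgb_gamma is None:
        rgb_gamma = colorspace.linear_to_srgb(rgb_linear)
    cone = colorspace.rgb_to_lms(rgb_linear)
    field = colorspace.lms_to_macleod_boynton(cone, wp)
    colorspace.saturation_and_hue(field)
    luv = colorspace.rgb_to_cieluv(rgb_linear)

    feats = chromatic.chromatic_features(field, luv)
    feats.update(
        spatial.spatial_features(
            _channels(field),
            rgb_gamma=rgb_gamma,
            seed=seed,
            eoe_max_edges=eoe_max_edges,
        )
    )
    return feats


def feature_table(
    images: dict[str, np.ndarray] | list[np.ndarray],
    seed: int = 0,
    eoe_max_edges: int = 10_000,
) -> pd.DataFrame:
    """Feature rows for a set of linear-RGB images, indexed by image id."""
    if isinstance(images, list):
        images = {f"img{i:03d}": im for i, im in enumerate(images)}
    rows = {name: image_features(im, seed=seed, eoe_max_edges=eoe_max_edges)
            for name, im in images.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image"
    return df
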