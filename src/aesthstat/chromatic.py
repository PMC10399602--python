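"""Chromatic image statistics.

Three families of statistics over the MacLeod-Boynton representation:

1. channel moments — mean and sample SD of l, s, luminance and saturation,
   plus RMS chromatic contrast in the CIE u*v* plane;
2. hue-segment statistics — the chromaticity plane is divided into eight
   45-degree radial segments centered on the equal-energy white, and each
   image yields per-segment pixel proportions and mean saturations
   (pixels below the 0.05 saturation floor or below the dark-luminance
   threshold are excluded);
3. natural chromatic distribution — a standard-deviation ellipse is fit
   to the pixel chromaticity cloud; its elongation along the -45-degree
   "natural chromatic" (blue-yellow / daylight) diagonal in a
   variance-normalized diagram, and the major-axis angle in the raw
   diagram, quantify how natural-scene-like the color distribution is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import ChromaticField, LuvField

__all__ = [
    "EllipseFit",
    "channel_moments",
    "luv_rms_contrast",
    "hue_segment_stats",
    "fit_sd_ellipse",
    "natural_chromatic_elongation",
    "ellipse_angle",
    "chromatic_features",
    "N_HUE_SEGMENTS",
    "SAT_FLOOR",
]

N_HUE_SEGMENTS = 8
SAT_FLOOR = 0.05


@dataclass
class EllipseFit:
    """Standard-deviation ellipse of a 2-D chromaticity cloud.

    ``axis_neg_diag`` / ``axis_orth`` are the SDs of the cloud projected
    onto the -45 and +45 degree diagonals; ``major_angle_deg`` is the
    major-axis orientation (eigenvector angle) in (-90, 90], relative to
    the +l axis.  ``sd_major``/``sd_minor`` are the eigenvalue square
    roots.
    """

    axis_neg_diag: float
    axis_orth: float
    major_angle_deg: float
    sd_major: float
    sd_minor: float
    normalized: bool


def _valid_pixels(field: ChromaticField) -> np.ndarray:
    return field.valid_chromatic()


def channel_moments(field: ChromaticField) -> dict[str, float]:
    """Means and sample SDs of l, s, luminance and saturation.

    Chromatic channels (l, s, sat) use only pixels passing the dark-pixel
    mask; luminance moments use every pixel.
    """
    if field.sat is None:
        raise ValueError("saturation not computed; call saturation_and_hue first")
    ok = _valid_pixels(field)
    if not ok.any():
        raise ValueError("no valid pixels after dark-pixel masking")
    out = {}
    for name, arr, mask in (
        ("l", field.l, ok),
        ("s", field.s, ok),
        ("sat", field.sat, ok),
        ("lum", field.lum, np.isfinite(field.lum)),
    ):
        v = arr[mask]
        out[f"mean_{name}"] = float(np.mean(v))
        out[f"sd_{name}"] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return out


def luv_rms_contrast(luv: LuvField) -> float:
    """RMS distance of each pixel from the mean chromaticity in (u*, v*).

    Lightness L* does not enter; the statistic is the root mean square of
    sqrt((u* - mean u*)^2 + (v* - mean v*)^2) over pixels.
    """
    u = np.ravel(luv.ustar)
    v = np.ravel(luv.vstar)
    if u.size == 0:
        raise ValueError("empty image")
    du = u - u.mean()
    dv = v - v.mean()
    return float(np.sqrt(np.mean(du**2 + dv**2)))


def hue_segment_stats(
    field: ChromaticField,
    n_segments: int = N_HUE_SEGMENTS,
    sat_floor: float = SAT_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment pixel proportions and mean saturations.

    Segments are ``360/n_segments`` degrees wide and centered at
    k * 360/n_segments (k = 0 .. n-1), counterclockwise from the +l
    direction.  Pixels failing the dark mask or with saturation below
    ``sat_floor`` are excluded.  With zero included pixels both outputs
    are all-NaN; empty segments get NaN mean saturation (absence, not
    zero saturation).
    """
    if field.hue is None or field.sat is None:
        raise ValueError("hue/saturation not computed")
    ok = _valid_pixels(field) & (field.sat >= sat_floor)
    props = np.full(n_segments, np.nan)
    msats = np.full(n_segments, np.nan)
    n_ok = int(ok.sum())
    if n_ok == 0:
        return props, msats
    width = 360.0 / n_segments
    # shift by half a width so segment k covers [k*w - w/2, k*w + w/2)
    seg = np.floor((field.hue[ok] + width / 2.0) / width).astype(int) % n_segments
    sat = field.sat[ok]
    for k in range(n_segments):
        in_k = seg == k
        props[k] = in_k.sum() / n_ok
        if in_k.any():
            msats[k] = sat[in_k].mean()
    return props, msats


def fit_sd_ellipse(l: np.ndarray, s: np.ndarray, normalize: bool = True) -> EllipseFit:
    """Fit the standard-deviation ellipse of a chromaticity cloud.

    With ``normalize`` each axis is divided by its own sample SD before
    fitting (the variance-normalized diagram used for elongation); the
    major-axis angle is only meaningful with ``normalize=False``.
    """
    x = np.ravel(np.asarray(l, dtype=np.float64))
    y = np.ravel(np.asarray(s, dtype=np.float64))
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 3:
        raise ValueError("need at least 3 points to fit an ellipse")
    x = x - x.mean()
    y = y - y.mean()
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (zero-variance) chromaticity cloud")
    if normalize:
        x = x / sx
        y = y / sy
    cov = np.cov(x, y, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    sd_minor, sd_major = np.sqrt(np.clip(evals, 0.0, None))
    vmajor = evecs[:, 1]
    ang = np.degrees(np.arctan2(vmajor[1], vmajor[0]))
    ang = (ang + 90.0) % 180.0 - 90.0  # fold into (-90, 90]
    if ang == -90.0:
        ang = 90.0
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    proj_neg = (x - y) * inv_sqrt2  # unit vector (1, -1)/sqrt(2)
    proj_pos = (x + y) * inv_sqrt2
    return EllipseFit(
        axis_neg_diag=float(proj_neg.std(ddof=1)),
        axis_orth=float(proj_pos.std(ddof=1)),
        major_angle_deg=float(ang),
        sd_major=float(sd_major),
        sd_minor=float(sd_minor),
        normalized=normalize,
    )


def natural_chromatic_elongation(fit: EllipseFit) -> float:
    """log(SD along the -45-degree natural chromatic axis / orthogonal SD).

    Zero for a circular cloud; positive when the cloud is elongated along
    the blue-yellow / daylight diagonal.  Natural logarithm.
    """
    if not fit.normalized:
        raise ValueError("elongation is defined in the variance-normalized diagram")
    if fit.axis_orth == 0:
        raise ValueError("zero orthogonal axis")
    return float(np.log(fit.axis_neg_diag / fit.axis_orth))


def ellipse_angle(fit: EllipseFit, circular_tol: float = 1e-9) -> float:
    """Major-axis angle (degrees in (-90, 90]) in the un-normalized diagram.

    NaN for circular clouds, whose orientation is undefined.
    """
    if fit.normalized:
        raise ValueError("ellipse angle is defined in the un-normalized diagram")
    if fit.sd_major - fit.sd_minor <= circular_tol * max(fit.sd_major, 1.0):
        return float("nan")
    return fit.major_angle_deg


def chromatic_features(field: ChromaticField, luv: LuvField) -> dict[str, float]:
    """All chromatic statistics of one image as a flat named mapping."""
    feats = dict(channel_moments(field))
    feats["luv_rms_contrast"] = luv_rms_contrast(luv)
    props, msats = hue_segment_stats(field)
    width = 360 // N_HUE_SEGMENTS
    for k in range(N_HUE_SEGMENTS):
        feats[f"hue_prop_seg{k * width}"] = float(props[k])
        feats[f"hue_sat_seg{k * width}"] = float(msats[k])
    ok = field.valid_chromatic()
    fit_norm = fit_sd_ellipse(field.l[ok], field.s[ok], normalize=True)
    fit_raw = fit_sd_ellipse(field.l[ok], field.s[ok], normalize=False)
    feats["natural_elongation"] = natural_chromatic_elongation(fit_norm)
    feats["ellipse_angle"] = ellipse_angle(fit_raw)
    return feats
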