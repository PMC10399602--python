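"""Cone-opponent color representation of images.

Converts RGB images to L, M, S cone excitations and to the MacLeod-Boynton
chromaticity diagram, whose axes are the cone-opponent dimensions
l = L/(L+M) ("teal-red") and s = S/(L+M) ("chartreuse-violet"), with
luminance L+M.  The equal-energy white point sits at (l, s) = (0.70, 1.0)
under the scaling convention adopted here, and saturation/hue are defined
as the radial distance / angle from that point.  A CIELUV conversion is
provided for the chromatic-contrast statistic.

All conversions operate on linear-light RGB in [0, 1]; 8/16-bit files are
assumed sRGB-encoded and are linearized on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "WhitePoint",
    "ConeImage",
    "ChromaticField",
    "LuvField",
    "load_rgb",
    "srgb_to_linear",
    "linear_to_srgb",
    "rgb_to_lms_matrix",
    "rgb_to_lms",
    "lms_to_macleod_boynton",
    "saturation_and_hue",
    "dark_pixel_mask",
    "rgb_to_xyz",
    "xyz_to_cieluv",
    "rgb_to_cieluv",
    "macleod_boynton_to_lms",
    "rescale_saturation_to_gamut",
    "cone_fundamentals",
    "lms_from_spectrum",
    "DARK_LUM_THRESHOLD",
    "EQUAL_ENERGY_XYZ",
]

#: Luminance threshold below which chromaticity is considered noise-dominated,
#: in units where the equal-energy white has L+M = 1.
DARK_LUM_THRESHOLD = 0.00045

# sRGB (IEC 61966-2-1) primaries, D65 white -> CIE XYZ, linear light.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Hunt-Pointer-Estevez XYZ -> LMS (equal-energy normalized variant).
_XYZ_TO_LMS_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)

EQUAL_ENERGY_XYZ = np.array([1.0, 1.0, 1.0])


@dataclass(frozen=True)
class WhitePoint:
    """Chromaticity of the equal-energy white in the scaled diagram."""

    l0: float = 0.70
    s0: float = 1.0


@dataclass
class ConeImage:
    """Per-pixel L, M, S cone excitations (linear radiance units)."""

    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    n_clipped: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape


@dataclass
class ChromaticField:
    """MacLeod-Boynton representation of an image.

    ``l`` and ``s`` are the cone-opponent chromaticities L/(L+M) and
    S/(L+M); ``lum`` is L+M.  ``sat`` and ``hue`` (degrees, [0, 360),
    counterclockwise from the +l direction) are measured from the white
    point.  ``dark_mask`` marks pixels too dark for reliable chromaticity;
    ``lowsat_mask`` marks pixels below the hue-filter saturation floor.
    """

    l: np.ndarray
    s: np.ndarray
    lum: np.ndarray
    sat: np.ndarray | None = None
    hue: np.ndarray | None = None
    dark_mask: np.ndarray | None = None
    lowsat_mask: np.ndarray | None = None
    white: WhitePoint = field(default_factory=WhitePoint)

    def valid_chromatic(self) -> np.ndarray:
        """Pixels usable for chromatic statistics (not dark, finite)."""
        ok = np.isfinite(self.l) & np.isfinite(self.s)
        if self.dark_mask is not None:
            ok &= ~self.dark_mask
        return ok


@dataclass
class LuvField:
    """CIE 1976 L*u*v* coordinates relative to a stated reference white."""

    Lstar: np.ndarray
    ustar: np.ndarray
    vstar: np.ndarray
    ref_white: np.ndarray = field(default_factory=lambda: EQUAL_ENERGY_XYZ.copy())


# ---------------------------------------------------------------------------
# image IO and gamma


def load_rgb(path, linearize: bool = True) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file to an H x W x 3 float array in [0, 1].

    8- or 16-bit integer channels are scaled to [0, 1]; with ``linearize``
    the sRGB transfer curve is inverted so downstream conversions operate
    on linear light.
    """
    with Image.open(path) as im:
        im = im.convert("RGB") if im.mode not in ("RGB", "I;16") else im
        arr = np.asarray(im, dtype=np.float64)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return srgb_to_linear(arr) if linearize else arr


def srgb_to_linear(rgb: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer function (gamma decoding)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    lo = rgb <= 0.04045
    out = np.empty_like(rgb)
    out[lo] = rgb[lo] / 12.92
    out[~lo] = ((rgb[~lo] + 0.055) / 1.055) ** 2.4
    return out


def linear_to_srgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.clip(np.asarray(rgb, dtype=np.float64), 0.0, 1.0)
    lo = rgb <= 0.0031308
    out = np.empty_like(rgb)
    out[lo] = rgb[lo] * 12.92
    out[~lo] = 1.055 * rgb[~lo] ** (1 / 2.4) - 0.055
    return out


# ---------------------------------------------------------------------------
# cone fundamentals (spectral path)


def cone_fundamentals(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Smooth synthetic L, M, S cone sensitivity curves, shape (n, 3).

    These are log-Gaussian approximations with peaks near 565, 540 and
    445 nm, standing in for tabulated cone fundamentals; they are used
    only through the equal-energy calibration below, which fixes the
    chromaticity scaling regardless of the exact curve shapes.
    """
    wl = np.asarray(wavelengths_nm, dtype=np.float64)
    peaks = np.array([565.0, 540.0, 445.0])
    widths = np.array([0.065, 0.062, 0.058])
    out = np.empty((wl.size, 3))
    for i, (p, w) in enumerate(zip(peaks, widths)):
        out[:, i] = np.exp(-0.5 * (np.log(wl / p) / w) ** 2)
    return out


def _equal_energy_scaling(lms_ee: np.ndarray, wp: WhitePoint) -> np.ndarray:
    """Per-cone gains mapping the equal-energy LMS to (l0, s0) with lum 1."""
    gl = wp.l0 / lms_ee[0]
    gm = (1.0 - wp.l0) / lms_ee[1]
    gs = wp.s0 / lms_ee[2]
    return np.array([gl, gm, gs])


def lms_from_spectrum(
    radiance: np.ndarray,
    wavelengths_nm: np.ndarray,
    wp: WhitePoint = WhitePoint(),
) -> np.ndarray:
    """Cone excitations of a radiance spectrum by 1-nm summation.

    The fundamentals are rescaled so that the equal-energy (flat)
    spectrum yields L+M = 1, L/(L+M) = ``wp.l0`` and S/(L+M) = ``wp.s0``.
    """
    fund = cone_fundamentals(wavelengths_nm)
    ee = fund.sum(axis=0)  # flat unit spectrum
    gains = _equal_energy_scaling(ee, wp)
    return (fund * radiance[:, None]).sum(axis=0) * gains


# ---------------------------------------------------------------------------
# matrix path


def rgb_to_lms_matrix(wp: WhitePoint = WhitePoint()) -> np.ndarray:
    """Default linear-sRGB -> LMS matrix under the equal-energy convention.

    Columns are the scaled LMS excitations of unit R, G, B.  The scaling
    puts the equal-energy stimulus (XYZ = (1,1,1)) at luminance L+M = 1
    with chromaticity (wp.l0, wp.s0).
    """
    m = _XYZ_TO_LMS_HPE @ _SRGB_TO_XYZ
    lms_ee = _XYZ_TO_LMS_HPE @ EQUAL_ENERGY_XYZ
    return _equal_energy_scaling(lms_ee, wp)[:, None] * m


def rgb_to_lms(img: np.ndarray, matrix: np.ndarray | None = None) -> ConeImage:
    """Convert a linear RGB image to cone excitations.

    Negative excitations (possible for saturated synthetic inputs) are
    clipped to zero; the clip count is recorded on the result.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("RGB image contains non-finite pixels")
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    if matrix is None:
        matrix = rgb_to_lms_matrix()
    lms = img @ matrix.T
    n_clipped = int(np.count_nonzero(lms < 0))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative cone excitations to 0")
        lms = np.clip(lms, 0.0, None)
    return ConeImage(L=lms[..., 0], M=lms[..., 1], S=lms[..., 2], n_clipped=n_clipped)


def lms_to_macleod_boynton(cone: ConeImage, wp: WhitePoint = WhitePoint()) -> ChromaticField:
    """MacLeod-Boynton chromaticities l = L/(L+M), s = S/(L+M), lum = L+M.

    Pixels with L+M = 0 have undefined chromaticity and are marked dark.
    """
    lum = cone.L + cone.M
    with np.errstate(divide="ignore", invalid="ignore"):
        l = np.where(lum > 0, cone.L / lum, np.nan)
        s = np.where(lum > 0, cone.S / lum, np.nan)
    field_ = ChromaticField(l=l, s=s, lum=lum, white=wp)
    field_.dark_mask = dark_pixel_mask(field_)
    return field_


def saturation_and_hue(
    field_: ChromaticField, wp: WhitePoint | None = None, sat_floor: float = 0.05
) -> ChromaticField:
    """Fill saturation (radial distance from white) and hue angle.

    Hue is measured counterclockwise from the +l direction, in degrees
    [0, 360), and is NaN where saturation is exactly zero.  ``sat_floor``
    marks the low-saturation pixels excluded from hue statistics.
    """
    wp = wp or field_.white
    dl = field_.l - wp.l0
    ds = field_.s - wp.s0
    sat = np.hypot(dl, ds)
    hue = np.degrees(np.arctan2(ds, dl)) % 360.0
    hue = np.where(sat > 0, hue, np.nan)
    field_.sat = sat
    field_.hue = hue
    field_.lowsat_mask = ~(sat >= sat_floor)  # NaN-safe: NaN counts as low-sat
    return field_


def dark_pixel_mask(field_: ChromaticField, threshold: float = DARK_LUM_THRESHOLD) -> np.ndarray:
    """Pixels with luminance strictly below ``threshold`` (chromaticity noise)."""
    if threshold <= 0:
        raise ValueError("dark-pixel threshold must be positive")
    return field_.lum < threshold


def macleod_boynton_to_lms(l, s, lum) -> ConeImage:
    """Invert the chromaticity mapping: L = l*lum, M = (1-l)*lum, S = s*lum."""
    l, s, lum = (np.asarray(a, dtype=np.float64) for a in (l, s, lum))
    return ConeImage(L=l * lum, M=(1.0 - l) * lum, S=s * lum)


# ---------------------------------------------------------------------------
# CIELUV


def rgb_to_xyz(img: np.ndarray) -> np.ndarray:
    """Linear sRGB -> CIE XYZ."""
    return np.asarray(img, dtype=np.float64) @ _SRGB_TO_XYZ.T


def xyz_to_cieluv(xyz: np.ndarray, ref_white: np.ndarray = EQUAL_ENERGY_XYZ) -> LuvField:
    """CIE 1976 L*u*v* from XYZ, relative to ``ref_white``.

    Uses the standard formulas: u' = 4X/(X+15Y+3Z), v' = 9Y/(X+15Y+3Z),
    L* from the cube-root lightness function, u* = 13 L* (u' - u'_n).
    """
    ref_white = np.asarray(ref_white, dtype=np.float64)
    if np.any(ref_white <= 0):
        raise ValueError("reference white must be strictly positive")
    xyz = np.asarray(xyz, dtype=np.float64)
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    Xn, Yn, Zn = ref_white

    yr = Y / Yn
    Lstar = np.where(yr > (6 / 29) ** 3, 116.0 * np.cbrt(yr) - 16.0, (29 / 3) ** 3 * yr)

    def _uv(X, Y, Z):
        d = X + 15.0 * Y + 3.0 * Z
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(d > 0, 4.0 * X / d, 0.0)
            v = np.where(d > 0, 9.0 * Y / d, 0.0)
        return u, v

    up, vp = _uv(X, Y, Z)
    upn, vpn = _uv(*ref_white)
    ustar = 13.0 * Lstar * (up - upn)
    vstar = 13.0 * Lstar * (vp - vpn)
    return LuvField(Lstar=Lstar, ustar=ustar, vstar=vstar, ref_white=ref_white)


def rgb_to_cieluv(img: np.ndarray, ref_white: np.ndarray = EQUAL_ENERGY_XYZ) -> LuvField:
    """Linear sRGB -> CIE L*u*v* via XYZ."""
    return xyz_to_cieluv(rgb_to_xyz(img), ref_white=ref_white)


# ---------------------------------------------------------------------------
# gamut rescaling


def rescale_saturation_to_gamut(
    fields: list[ChromaticField],
    in_gamut,
    tol: float = 1e-6,
) -> tuple[list[ChromaticField], float]:
    """Scale all pixels' radial saturation by one global factor into gamut.

    ``in_gamut(l, s, lum)`` is a vectorized predicate over chromaticity
    triples.  The factor is the maximal value <= 1 (found by bisection)
    such that every pixel of every field passes the predicate.  Returns
    the rescaled fields and the factor.
    """
    for f in fields:
        if f.sat is None:
            saturation_and_hue(f)
    wp = fields[0].white
    if not np.all(in_gamut(np.array([wp.l0]), np.array([wp.s0]), np.array([1.0]))):
        raise ValueError("gamut predicate rejects the white point")

    def _ok(factor: float) -> bool:
        for f in fields:
            l = wp.l0 + factor * (f.l - wp.l0)
            s = wp.s0 + factor * (f.s - wp.s0)
            m = np.isfinite(l)
            if not np.all(in_gamut(l[m], s[m], f.lum[m])):
                return False
        return True

    if _ok(1.0):
        factor = 1.0
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _ok(mid):
                lo = mid
            else:
                hi = mid
        factor = lo

    out = []
    for f in fields:
        g = ChromaticField(
            l=wp.l0 + factor * (f.l - wp.l0),
            s=wp.s0 + factor * (f.s - wp.s0),
            lum=f.lum.copy(),
            white=wp,
        )
        g.dark_mask = dark_pixel_mask(g)
        saturation_and_hue(g)
        out.append(g)
    return out, factor
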