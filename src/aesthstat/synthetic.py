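"""Synthetic images and behavioral data with planted ground truth.

Every pipeline stage can be verified against construction: images are
synthesized with a known amplitude-spectrum exponent, known chromaticity
ellipse (center, axis SDs, orientation) around the equal-energy white,
and known fractal structure; behavioral tables are generated from a
planted linear combination of z-scored image statistics plus Gaussian
noise, through a truncated-Gaussian looking-time model for infants and a
Bradley-Terry (logistic) choice model for adults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavioral
from .colorspace import WhitePoint, macleod_boynton_to_lms, rgb_to_lms_matrix

__all__ = [
    "ImageSpec",
    "BehavioralSpec",
    "make_spectral_image",
    "make_chromatic_field_image",
    "make_fractal_fixture",
    "make_corpus",
    "make_behavioral_dataset",
    "planted_elongation",
    "ellipse_covariance",
]


@dataclass
class ImageSpec:
    """Recipe for one synthetic painting-like image.

    The chromaticity cloud is a bivariate Gaussian in (l, s) with the
    given axis SDs and major-axis angle (degrees, un-normalized diagram)
    about ``center``; luminance and the chromatic fields share a
    random-phase spectral structure with amplitude exponent ``beta``.
    """

    size: int = 128
    beta: float = -1.0
    center: tuple[float, float] = (0.70, 1.0)
    sd_major: float = 0.006
    sd_minor: float = 0.002
    angle_deg: float = -45.0
    mean_lum: float = 0.45
    lum_range: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.sd_major <= 0 or self.sd_minor <= 0:
            raise ValueError("ellipse SDs must be positive")


@dataclass
class BehavioralSpec:
    """Recipe for planted feature-preference behavioral data."""

    coefficients: dict[str, float]
    noise_sd: float = 0.5
    n_infants: int = 20
    n_adults: int = 20
    subset_size: int = 10
    look_baseline_s: float = 2.5
    look_scale_s: float = 0.6
    look_trial_sd_s: float = 0.8
    choice_slope: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")


# ---------------------------------------------------------------------------
# spectral fields


def _spectral_field(size: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Random-phase field with amplitude ~ f^beta, zero mean, unit SD."""
    fx = np.fft.fftfreq(size) * size
    f = np.hypot(*np.meshgrid(fx, fx, indexing="ij"))
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** beta
    phase = rng.uniform(0, 2 * np.pi, f.shape)
    spec = amp * np.exp(1j * phase)
    img = np.real(np.fft.ifft2(spec))
    return (img - img.mean()) / img.std()


def make_spectral_image(size: int, beta: float, seed: int = 0) -> np.ndarray:
    """Random-phase image with planted spectral exponent, scaled to [0, 1]."""
    if size % 2:
        raise ValueError("size must be even")
    if beta > 0:
        raise ValueError("spectral exponent must be <= 0")
    rng = np.random.default_rng(seed)
    img = _spectral_field(size, beta, rng)
    return (img - img.min()) / np.ptp(img)


# ---------------------------------------------------------------------------
# chromaticity ellipse plumbing


def ellipse_covariance(sd_major: float, sd_minor: float, angle_deg: float) -> np.ndarray:
    """2x2 covariance with the given axis SDs and major-axis angle."""
    t = np.radians(angle_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return R @ np.diag([sd_major**2, sd_minor**2]) @ R.T


def planted_elongation(sd_major: float, sd_minor: float, angle_deg: float) -> float:
    """Expected natural chromatic elongation of the planted ellipse.

    Variance-normalizing each axis turns the planted covariance into its
    correlation matrix, for which the SDs along the -45/+45 diagonals are
    sqrt(1 -/+ rho); the elongation is therefore 0.5*log((1-rho)/(1+rho)).
    """
    C = ellipse_covariance(sd_major, sd_minor, angle_deg)
    rho = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
    return float(0.5 * np.log((1.0 - rho) / (1.0 + rho)))


def make_chromatic_field_image(spec: ImageSpec, clip: bool = False) -> np.ndarray:
    """Linear RGB image with planted chromaticity ellipse and spectral slope.

    Two independent spectral fields are mixed by the Cholesky factor of
    the planted (l, s) covariance, so pixel chromaticities follow the
    requested Gaussian cloud while retaining spatial structure; luminance
    is a third spectral field spanning ``mean_lum +/- lum_range/2``.
    Raises if any resulting pixel leaves the RGB gamut.
    """
    rng = np.random.default_rng(spec.seed)
    C = ellipse_covariance(spec.sd_major, spec.sd_minor, spec.angle_deg)
    A = np.linalg.cholesky(C)
    f1 = _spectral_field(spec.size, spec.beta, rng)
    f2 = _spectral_field(spec.size, spec.beta, rng)
    # steep-spectrum fields have few effective degrees of freedom, so two
    # independent draws can be strongly sample-correlated; orthogonalize
    # so the realized pixel covariance matches the request, not just its
    # expectation
    f2 = f2 - (f1.ravel() @ f2.ravel()) / (f1.ravel() @ f1.ravel()) * f1
    f2 = (f2 - f2.mean()) / f2.std()
    l = spec.center[0] + A[0, 0] * f1 + A[0, 1] * f2
    s = spec.center[1] + A[1, 0] * f1 + A[1, 1] * f2
    flum = _spectral_field(spec.size, spec.beta, rng)
    flum = (flum - flum.min()) / np.ptp(flum) - 0.5  # [-0.5, 0.5]
    lum = spec.mean_lum + spec.lum_range * flum
    cone = macleod_boynton_to_lms(l, s, lum)
    M = rgb_to_lms_matrix()
    lms = np.stack([cone.L, cone.M, cone.S], axis=-1)
    rgb = lms @ np.linalg.inv(M).T
    if rgb.min() < -1e-9 or rgb.max() > 1 + 1e-9:
        if not clip:
            raise ValueError(
                "planted chromaticity/luminance leaves the RGB gamut; "
                "reduce the ellipse SDs (saturation scale) or luminance range"
            )
    return np.clip(rgb, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fractal fixtures


def make_fractal_fixture(kind: str, size: int = 256, **params):
    """Deterministic rasters / seeded surfaces with known fractal dimension.

    ``line`` and ``sierpinski`` return binary edge masks (box-counting
    dimension 1 and log3/log2); ``filled`` returns an all-true mask
    (dimension 2); ``fbm`` returns a fractional-Brownian surface with
    Hurst exponent ``hurst`` (surface dimension 3 - H).
    """
    if kind == "line":
        m = np.zeros((size, size), dtype=bool)
        m[size // 2, :] = True
        return m
    if kind == "filled":
        return np.ones((size, size), dtype=bool)
    if kind == "sierpinski":
        levels = params.get("levels", 8)
        n = 2**levels
        if n > size:
            raise ValueError(f"{levels} subdivision levels exceed size {size}")
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return (i & j) == 0
    if kind == "fbm":
        hurst = params.get("hurst", 0.5)
        seed = params.get("seed", 0)
        rng = np.random.default_rng(seed)
        # power ~ f^-(2H+2) => amplitude exponent -(H+1)
        surf = _spectral_field(size, -(hurst + 1.0), rng)
        return (surf - surf.min()) / np.ptp(surf)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# corpora and behavior


def make_corpus(
    n_images: int = 40,
    size: int = 128,
    seed: int = 0,
    wp: WhitePoint = WhitePoint(),
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """A set of synthetic paintings with varied planted parameters.

    Spectral exponent, ellipse elongation/angle, saturation scale and
    luminance spread vary smoothly across the corpus so that every image
    statistic has real between-image variance.  Returns the linear-RGB
    images and a manifest of the planted parameters per image.
    """
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for i in range(n_images):
        beta = rng.uniform(-1.6, -0.6)
        # chromatic cloud: offsets and spread mostly along the s axis (the
        # RGB gamut is narrow in l, wide in s), with the negative l-s
        # correlation typical of natural scenes
        sd_l = rng.uniform(0.003, 0.012)
        sd_s = rng.uniform(0.04, 0.12)
        rho = rng.uniform(-0.8, 0.3)
        C = np.array([[sd_l**2, rho * sd_l * sd_s], [rho * sd_l * sd_s, sd_s**2]])
        evals, evecs = np.linalg.eigh(C)
        angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
        angle = (angle + 90.0) % 180.0 - 90.0
        sd_major, sd_minor = float(np.sqrt(evals[1])), float(np.sqrt(evals[0]))
        center = (
            wp.l0 + rng.uniform(-0.015, 0.015),
            wp.s0 + rng.uniform(-0.25, 0.35),
        )
        mean_lum = rng.uniform(0.3, 0.45)
        lum_range = rng.uniform(0.25, 0.45)
        spec = ImageSpec(
            size=size,
            beta=beta,
            center=center,
            sd_major=sd_major,
            sd_minor=sd_minor,
            angle_deg=angle,
            mean_lum=mean_lum,
            lum_range=lum_range,
            seed=int(rng.integers(2**31 - 1)),
        )
        images.append(make_chromatic_field_image(spec, clip=True))
        rows.append(
            {
                "image": f"img{i:03d}",
                "beta": beta,
                "sd_major": sd_major,
                "sd_minor": sd_minor,
                "angle_deg": angle,
                "mean_lum": mean_lum,
                "lum_range": lum_range,
                "elongation": planted_elongation(sd_major, sd_minor, angle),
                "seed": spec.seed,
            }
        )
    return images, pd.DataFrame(rows).set_index("image")


def latent_values(
    features: pd.DataFrame, spec: BehavioralSpec, rng: np.random.Generator
) -> pd.Series:
    """Planted per-image value v = sum_j coef_j z_j + Gaussian noise."""
    missing = set(spec.coefficients) - set(features.columns)
    if missing:
        raise ValueError(f"coefficients reference absent features: {sorted(missing)}")
    v = pd.Series(0.0, index=features.index)
    for name, coef in spec.coefficients.items():
        col = features[name]
        z = (col - col.mean()) / col.std(ddof=1)
        v = v + coef * z
    v = v + rng.normal(0.0, spec.noise_sd, len(v))
    return v.rename("latent")


def _assign_subsets(
    images: list, n_participants: int, subset_size: int, rng: np.random.Generator
) -> list[list]:
    """Partition images into subsets of ``subset_size`` (seeded shuffle)
    and assign participants round-robin so every image is covered."""
    perm = list(rng.permutation(images))
    blocks = [perm[i : i + subset_size] for i in range(0, len(perm), subset_size)]
    blocks = [b for b in blocks if len(b) >= 2]
    if n_participants < len(blocks):
        raise ValueError(
            f"need at least {len(blocks)} participants to cover all images"
        )
    return [blocks[i % len(blocks)] for i in range(n_participants)]


def make_behavioral_dataset(
    spec: BehavioralSpec, features: pd.DataFrame
) -> dict[str, object]:
    """Trial-level infant looking and adult choice tables with planted truth.

    Infant looking per side is a truncated Gaussian around the baseline
    shifted by the presented image's latent value; adult choices are
    Bernoulli with logistic probability in the latent difference.
    Returns a dict with ``infant_trials``, ``adult_trials``, ``latent``,
    ``assignments`` and the per-image expected looking times.
    """
    rng = np.random.default_rng(spec.seed)
    v = latent_values(features, spec, rng)
    images = list(features.index)

    infant_rows = []
    infant_sets = _assign_subsets(images, spec.n_infants, spec.subset_size, rng)
    for pid, subset in enumerate(infant_sets):
        design = behavioral.generate_pair_design(subset, seed=int(rng.integers(2**31 - 1)))
        for _, t in design.trials.iterrows():
            looks = {}
            for side, img in (("left", t["left"]), ("right", t["right"])):
                mu = spec.look_baseline_s + spec.look_scale_s * v[img]
                x = rng.normal(mu, spec.look_trial_sd_s)
                looks[side] = float(np.clip(x, 0.0, behavioral.TRIAL_DURATION_S))
            infant_rows.append(
                {
                    "participant": f"infant{pid:03d}",
                    "trial": int(t["trial"]),
                    "left": t["left"],
                    "right": t["right"],
                    "look_left_s": looks["left"],
                    "look_right_s": looks["right"],
                }
            )

    adult_rows = []
    adult_sets = _assign_subsets(images, spec.n_adults, spec.subset_size, rng)
    for pid, subset in enumerate(adult_sets):
        design = behavioral.generate_pair_design(subset, seed=int(rng.integers(2**31 - 1)))
        for _, t in design.trials.iterrows():
            dv = spec.choice_slope * (v[t["left"]] - v[t["right"]])
            p_left = 1.0 / (1.0 + np.exp(-dv))
            side = "left" if rng.random() < p_left else "right"
            adult_rows.append(
                {
                    "participant": f"adult{pid:03d}",
                    "trial": int(t["trial"]),
                    "left": t["left"],
                    "right": t["right"],
                    "chosen_side": side,
                }
            )

    return {
        "infant_trials": pd.DataFrame(infant_rows),
        "adult_trials": pd.DataFrame(adult_rows),
        "latent": v,
        "infant_subsets": infant_sets,
        "adult_subsets": adult_sets,
    }
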