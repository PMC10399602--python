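"""End-to-end orchestration: extract features, aggregate scores, fit models.

``run_extract`` walks an image directory (non-square inputs are center
cropped to the largest square and rescaled with bicubic interpolation),
computes the full statistic battery and writes a per-image CSV with a
metadata sidecar.  ``run_model`` joins the feature table with per-image
scores and runs the backward-elimination regression, the PLSR with VIP
scores, and the permutation null, serializing the results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import behavioral, colorspace, features, models, synthetic

__all__ = ["RunConfig", "prepare_image", "run_extract", "run_model", "run_simulate"]

log = logging.getLogger("aesthstat")

IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the analysis conventions
    (elimination p 0.1, VIF and VIP thresholds 1.25)."""

    image_size: int = 550
    white_point: tuple[float, float] = (0.70, 1.0)
    dark_threshold: float = colorspace.DARK_LUM_THRESHOLD
    sat_floor: float = 0.05
    p_threshold: float = 0.1
    vif_threshold: float = 1.25
    vip_threshold: float = 1.25
    n_perm: int = 10_000
    eoe_max_edges: int = 10_000
    seed: int = 0
    feature_subset: list[str] | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def prepare_image(arr: np.ndarray, size: int) -> np.ndarray:
    """Center-crop to the largest square and rescale (bicubic)."""
    h, w = arr.shape[:2]
    side = min(h, w)
    r0, c0 = (h - side) // 2, (w - side) // 2
    sq = arr[r0 : r0 + side, c0 : c0 + side]
    if side != size:
        sq = resize(sq, (size, size) + sq.shape[2:], order=3, anti_aliasing=side > size)
    return np.clip(sq, 0.0, 1.0)


def run_extract(image_dir, cfg: RunConfig | None = None, out_csv=None) -> pd.DataFrame:
    """Feature CSV for every readable image under ``image_dir``."""
    cfg = cfg or RunConfig()
    paths = sorted(p for p in Path(image_dir).iterdir() if p.suffix.lower() in IMAGE_EXTS)
    rows = {}
    for p in paths:
        t0 = time.perf_counter()
        try:
            gamma = colorspace.load_rgb(p, linearize=False)
        except Exception as e:  # unreadable image: skip, keep going
            log.error("skipping unreadable image %s: %s", p.name, e)
            continue
        gamma = prepare_image(gamma, cfg.image_size)
        linear = colorspace.srgb_to_linear(gamma)
        feats = features.image_features(
            linear, rgb_gamma=gamma, seed=cfg.seed, eoe_max_edges=cfg.eoe_max_edges
        )
        if cfg.feature_subset:
            feats = {k: v for k, v in feats.items() if k in set(cfg.feature_subset)}
        rows[p.stem] = feats
        log.info("extracted %s in %.2fs", p.name, time.perf_counter() - t0)
    if not rows:
        raise ValueError(f"no readable images in {image_dir}")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image"
    if out_csv:
        df.to_csv(out_csv)
        _write_sidecar(Path(out_csv), cfg)
    return df


def _write_sidecar(out: Path, cfg: RunConfig) -> None:
    import skimage
    import sklearn
    import statsmodels

    meta = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    out.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=str))


def run_model(
    feats: pd.DataFrame,
    scores: pd.Series,
    cfg: RunConfig | None = None,
    method: str = "both",
    out_dir=None,
) -> dict:
    """Fit the preference models on a feature table and per-image scores."""
    cfg = cfg or RunConfig()
    orphans_f = set(feats.index) - set(scores.index)
    orphans_s = set(scores.index) - set(feats.index)
    if orphans_f or orphans_s:
        raise ValueError(
            f"image key mismatch; features-only: {sorted(orphans_f)[:5]}, "
            f"scores-only: {sorted(orphans_s)[:5]}"
        )
    feats = feats.dropna(axis=1)  # statistics undefined on this corpus
    flat = feats.columns[feats.std(ddof=1) == 0]
    if len(flat):
        log.info("dropping zero-variance features: %s", list(flat))
        feats = feats.drop(columns=flat)  # no between-image information
    out: dict = {"config_hash": cfg.config_hash()}
    if method in ("mlr", "both"):
        mlr = models.PreferenceRegression(
            feats, scores, p_threshold=cfg.p_threshold, vif_threshold=cfg.vif_threshold
        ).fit()
        out["mlr"] = mlr
    if method in ("plsr", "both"):
        pls_model = models.PLSPreference(feats, scores, vip_threshold=cfg.vip_threshold)
        pls = pls_model.fit()
        out["plsr"] = pls
        if cfg.n_perm:
            out["permutation"] = pls_model.permutation_null(
                n_permutations=cfg.n_perm, seed=cfg.seed
            )
    if out_dir:
        _serialize_results(Path(out_dir), out)
    return out


def _serialize_results(out_dir: Path, results: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if "mlr" in results:
        m = results["mlr"]
        payload = {
            "retained": m.retained,
            "beta": m.params.to_dict(),
            "t": m.tvalues.to_dict(),
            "p": m.pvalues.to_dict(),
            "F": m.fvalue,
            "df": [m.df_model, m.df_resid],
            "adj_r2": m.rsquared_adj,
            "vif": m.vifs.to_dict(),
            "trace": m.elimination_trace,
            "config_hash": results["config_hash"],
        }
        (out_dir / "mlr_result.json").write_text(json.dumps(payload, indent=2, default=str))
    if "plsr" in results:
        p = results["plsr"]
        payload = {
            "n_components": p.n_components,
            "pct_variance_explained": p.pct_variance_explained,
            "vip": p.vip.to_dict(),
            "sign": p.signs.to_dict(),
            "config_hash": results["config_hash"],
        }
        (out_dir / "plsr_result.json").write_text(json.dumps(payload, indent=2, default=str))
    if "permutation" in results:
        s = results["permutation"]
        pd.DataFrame({"pct_variance_explained": s.null}).to_csv(
            out_dir / "permutation_null.csv", index=False
        )
        (out_dir / "permutation_summary.json").write_text(
            json.dumps(
                {
                    "n_permutations": s.n_permutations,
                    "null_mean": s.mean,
                    "null_sd": s.sd,
                    "null_min": s.min,
                    "null_max": s.max,
                    "observed": s.observed,
                    "z": s.zscore,
                    "p": s.pvalue,
                    "config_hash": results["config_hash"],
                },
                indent=2,
            )
        )


def run_simulate(
    out_dir,
    n_images: int = 40,
    size: int = 128,
    coefficients: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    n_infants: int = 20,
    n_adults: int = 20,
    seed: int = 0,
) -> dict:
    """Write a synthetic corpus: images, behavioral CSVs and truth manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    images, manifest = synthetic.make_corpus(n_images=n_images, size=size, seed=seed)
    named = {f"img{i:03d}": im for i, im in enumerate(images)}
    for name, im in named.items():
        arr = (colorspace.linear_to_srgb(im) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(out_dir / "images" / f"{name}.png")
    feats = features.feature_table(named, seed=seed)
    feats.to_csv(out_dir / "features.csv")
    coefficients = coefficients or {
        "sd_sat": 0.8,
        "spectral_slope_lum": 0.5,
        "entropy_l": -0.5,
    }
    bspec = synthetic.BehavioralSpec(
        coefficients=coefficients,
        noise_sd=noise_sd,
        n_infants=n_infants,
        n_adults=n_adults,
        seed=seed,
    )
    data = synthetic.make_behavioral_dataset(bspec, feats)
    data["infant_trials"].to_csv(out_dir / "infant_looks.csv", index=False)
    data["adult_trials"].to_csv(out_dir / "adult_choices.csv", index=False)
    looking = behavioral.aggregate_looking(data["infant_trials"])
    pleas = behavioral.aggregate_pleasantness(data["adult_trials"])
    pd.DataFrame({"image": looking.index, "score": looking.values}).to_csv(
        out_dir / "infant_scores.csv", index=False
    )
    pd.DataFrame({"image": pleas.index, "score": pleas.values}).to_csv(
        out_dir / "adult_scores.csv", index=False
    )
    manifest = manifest.join(data["latent"])
    manifest.to_csv(out_dir / "truth.csv")
    (out_dir / "truth.json").write_text(
        json.dumps(
            {
                "coefficients": coefficients,
                "noise_sd": noise_sd,
                "n_infants": n_infants,
                "n_adults": n_adults,
                "seed": seed,
            },
            indent=2,
        )
    )
    return {
        "features": feats,
        "looking": looking,
        "pleasantness": pleas,
        "latent": data["latent"],
    }
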