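"""Paired-presentation design and behavioral score aggregation.

Each participant sees a subset of k images (default 10) in a complete
round-robin of C(k, 2) pairs — 45 trials for k = 10 — with random
left/right placement and randomized trial order.  Infant preference is
measured as looking time per 5-second trial; adult preference as a
forced choice of the more pleasant image.  Scores aggregate in two
stages: per-participant per-image mean (looking seconds, or proportion
of that image's trials in which it was chosen), then an unweighted mean
across participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairDesign",
    "generate_pair_design",
    "aggregate_looking",
    "aggregate_pleasantness",
    "correlate_scores",
    "interrater_reliability",
    "TRIAL_DURATION_S",
    "DEFAULT_SUBSET_SIZE",
]

TRIAL_DURATION_S = 5.0
DEFAULT_SUBSET_SIZE = 10


@dataclass
class PairDesign:
    """Round-robin pairing of a stimulus subset.

    ``trials`` is a DataFrame with columns (trial, left, right): every
    unordered pair of ``subset`` exactly once, sides and order randomized
    by ``seed``.
    """

    trials: pd.DataFrame
    subset: list
    seed: int

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def generate_pair_design(subset, seed: int = 0) -> PairDesign:
    """All C(k, 2) pairs of ``subset`` with random sides and order."""
    subset = list(subset)
    if len(subset) != len(set(subset)):
        raise ValueError("duplicate image ids in subset")
    if len(subset) < 2:
        raise ValueError("need at least 2 images")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(subset, 2))
    rows = []
    for a, b in pairs:
        left, right = (a, b) if rng.random() < 0.5 else (b, a)
        rows.append((left, right))
    order = rng.permutation(len(rows))
    trials = pd.DataFrame(
        [(int(t), *rows[i]) for t, i in enumerate(order)],
        columns=["trial", "left", "right"],
    )
    return PairDesign(trials=trials, subset=subset, seed=seed)


def _trial_sides(responses: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "trial", "left", "right"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return responses


def aggregate_looking(responses: pd.DataFrame) -> pd.Series:
    """Mean looking time per image, two-stage.

    ``responses`` rows: (participant, trial, left, right, look_left_s,
    look_right_s).  Looking at an image is averaged over all its
    presentations (left and right) within each infant — skipped trials
    are simply absent from the denominator — and then across infants.
    Returns a Series indexed by image id, in seconds.
    """
    responses = _trial_sides(responses)
    bad = (
        (responses["look_left_s"] < 0)
        | (responses["look_right_s"] < 0)
        | (responses["look_left_s"] > TRIAL_DURATION_S)
        | (responses["look_right_s"] > TRIAL_DURATION_S)
    )
    if bad.any():
        raise ValueError("looking times must lie in [0, 5] seconds")
    long = pd.concat(
        [
            responses.rename(columns={"left": "image", "look_left_s": "look"})[
                ["participant", "image", "look"]
            ],
            responses.rename(columns={"right": "image", "look_right_s": "look"})[
                ["participant", "image", "look"]
            ],
        ]
    ).dropna(subset=["look"])
    per_infant = long.groupby(["participant", "image"])["look"].mean()
    return per_infant.groupby("image").mean().rename("looking_s")


def aggregate_pleasantness(responses: pd.DataFrame) -> pd.Series:
    """Proportion of trials each image was chosen, two-stage.

    ``responses`` rows: (participant, trial, left, right, chosen_side in
    {left, right}).  Per adult, each image's score is the fraction of its
    trials in which it was chosen; trials without a recorded choice are
    dropped from numerator and denominator with a warning.  Scores are
    then averaged across adults; the result lies in [0, 1].
    """
    import warnings

    responses = _trial_sides(responses)
    n_missing = responses["chosen_side"].isna().sum()
    if n_missing:
        warnings.warn(f"dropping {n_missing} trials without a recorded choice")
        responses = responses.dropna(subset=["chosen_side"])
    bad = ~responses["chosen_side"].isin(["left", "right"])
    if bad.any():
        raise ValueError("chosen_side must be 'left' or 'right'")
    chosen = np.where(
        responses["chosen_side"] == "left", responses["left"], responses["right"]
    )
    long = pd.concat(
        [
            responses.assign(image=responses["left"]),
            responses.assign(image=responses["right"]),
        ]
    )
    long["won"] = np.concatenate([chosen == responses["left"], chosen == responses["right"]])
    per_adult = long.groupby(["participant", "image"])["won"].mean()
    return per_adult.groupby("image").mean().rename("pleasantness")


def correlate_scores(x: pd.Series, y: pd.Series) -> tuple[float, int, float]:
    """Pearson correlation of two per-image score vectors.

    Aligns on the shared image index; returns (r, n, two-sided p).
    """
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 paired scores")
    if joined["x"].std() == 0 or joined["y"].std() == 0:
        raise ValueError("zero-variance scores")
    r, p = stats.pearsonr(joined["x"], joined["y"])
    return float(r), n, float(p)


def interrater_reliability(coder_a: pd.Series, coder_b: pd.Series) -> float:
    """Pearson r between two coders' per-image scores on the double-coded set."""
    r, _, _ = correlate_scores(coder_a, coder_b)
    return r
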