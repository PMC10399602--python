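"""Models linking image statistics to preference scores.

Two complementary model families, both on z-scored predictors and outcome:

* :class:`PreferenceRegression` — ordinary least squares with backward
  elimination (predictors removed while any coefficient p exceeds 0.1)
  followed by variance-inflation-factor pruning (highest-VIF predictor
  removed until all VIFs < 1.25).  This is the conventional approach:
  collinear predictors are dropped.
* :class:`PLSPreference` — partial least squares regression (PLS1),
  which tolerates collinearity by projecting the predictors onto latent
  components that maximize covariance with the outcome.  The component
  count is chosen by leave-one-out cross-validation; variable importance
  in projection (VIP) scores rank predictors, with VIP > 1.25 flagged as
  important.  A permutation test (outcome shuffled, components re-selected
  per permutation) provides the null distribution of variance explained.

Both follow the Model -> fit() -> Results pattern: the Results objects
carry estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "zscore",
    "vif",
    "screen_variables",
    "PreferenceRegression",
    "PreferenceRegressionResults",
    "PLSPreference",
    "PLSPreferenceResults",
    "PermutationSummary",
    "backward_eliminate",
    "fit_mlr",
    "plsr_fit",
    "permutation_null",
    "P_THRESHOLD",
    "VIF_THRESHOLD",
    "VIP_THRESHOLD",
]

P_THRESHOLD = 0.1
VIF_THRESHOLD = 1.25
VIP_THRESHOLD = 1.25


# ---------------------------------------------------------------------------
# table preparation


def zscore(tbl: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Standardize columns to mean 0, sample SD 1.

    Raises on zero-variance columns, naming the offender.
    """
    if isinstance(tbl, pd.Series):
        sd = tbl.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {tbl.name!r} has zero or undefined variance")
        return (tbl - tbl.mean()) / sd
    out = {}
    for c in tbl.columns:
        out[c] = zscore(tbl[c])
    return pd.DataFrame(out, index=tbl.index)


def vif(tbl: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column.

    VIF_j = 1/(1 - R^2_j) with R^2_j from regressing column j on all the
    other columns (with intercept); infinite for perfectly collinear
    columns.
    """
    if tbl.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    out = {}
    for c in tbl.columns:
        others = sm.add_constant(tbl.drop(columns=c).to_numpy())
        r2 = sm.OLS(tbl[c].to_numpy(), others).fit().rsquared
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def screen_variables(
    tbl: pd.DataFrame,
    y: pd.Series,
    cook_frac: float = 4.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag features whose apparent relationship with y hinges on an
    influential observation.

    For each feature, a univariate regression of y on the feature is
    examined; observations with Cook's distance > ``cook_frac``/n are
    influential candidates.  A feature is excluded only when its apparent
    relationship hinges on that single observation: the feature is
    significant at ``alpha`` with the observation included but loses
    significance (or flips sign) once it is deleted.  Returns the
    screened table and a report (feature, max Cook's D, reason) of
    removals.
    """
    n = len(y)
    removed = []
    keep = []
    for c in tbl.columns:
        x = sm.add_constant(tbl[c].to_numpy())
        fit = sm.OLS(y.to_numpy(), x).fit()
        cooks = fit.get_influence().cooks_distance[0]
        worst = int(np.argmax(cooks))
        if cooks[worst] > cook_frac / n and fit.pvalues[1] < alpha:
            sub = np.delete(np.arange(n), worst)
            refit = sm.OLS(y.to_numpy()[sub], x[sub]).fit()
            sig_flip = refit.pvalues[1] >= alpha
            sign_flip = np.sign(fit.params[1]) != np.sign(refit.params[1])
            if sig_flip or sign_flip:
                removed.append(
                    {
                        "feature": c,
                        "max_cooks_d": float(cooks[worst]),
                        "observation": tbl.index[worst],
                        "reason": "sign flip" if sign_flip else "significance flip",
                    }
                )
                continue
        keep.append(c)
    report = pd.DataFrame(removed, columns=["feature", "max_cooks_d", "observation", "reason"])
    return tbl[keep], report


# ---------------------------------------------------------------------------
# backward-elimination multiple regression


@dataclass
class PreferenceRegressionResults:
    """OLS results after backward elimination and VIF pruning."""

    retained: list[str]
    params: pd.Series  # standardized betas
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    df_model: int
    df_resid: int
    f_pvalue: float
    rsquared: float
    rsquared_adj: float
    vifs: pd.Series
    elimination_trace: list[dict] = field(default_factory=list)
    screen_report: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "Backward-elimination multiple regression (standardized)",
            "=" * 60,
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f},"
            f" p = {self.f_pvalue:.4g}, adj. R^2 = {self.rsquared_adj:.3f}",
            "-" * 60,
            f"{'predictor':<28}{'beta':>8}{'t':>8}{'p':>8}{'VIF':>7}",
        ]
        for c in self.retained:
            lines.append(
                f"{c:<28}{self.params[c]:>8.3f}{self.tvalues[c]:>8.3f}"
                f"{self.pvalues[c]:>8.3f}{self.vifs.get(c, float('nan')):>7.2f}"
            )
        return "\n".join(lines)


class PreferenceRegression:
    """Backward-elimination OLS of a preference score on image statistics.

    Parameters
    ----------
    features : DataFrame
        Per-image predictors (z-scored internally unless ``standardize``
        is False).
    y : Series
        Per-image outcome (looking seconds or pleasantness proportion).
    p_threshold, vif_threshold : float
        Removal thresholds for elimination and collinearity pruning.
    screen : bool
        Apply the influential-outlier feature screen before fitting.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        y: pd.Series,
        p_threshold: float = P_THRESHOLD,
        vif_threshold: float = VIF_THRESHOLD,
        screen: bool = True,
        standardize: bool = True,
        forced_entry: bool = False,
    ):
        features, y = features.align(y, join="inner", axis=0)
        if features.isna().any().any() or y.isna().any():
            raise ValueError("features/outcome contain missing values")
        self.p_threshold = p_threshold
        self.vif_threshold = vif_threshold
        self.screen = screen
        self.forced_entry = forced_entry
        if standardize:
            features = zscore(features)
            y = zscore(y)
        self.features = features
        self.y = y

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, **kw) -> "PreferenceRegression":
        return cls(df.drop(columns=outcome), df[outcome], **kw)

    def _ols(self, cols: list[str]):
        X = sm.add_constant(self.features[cols].to_numpy())
        return sm.OLS(self.y.to_numpy(), X).fit()

    def fit(self) -> PreferenceRegressionResults:
        tbl = self.features
        screen_report = None
        if self.screen:
            tbl, screen_report = screen_variables(tbl, self.y)
        n = len(self.y)
        trace: list[dict] = []
        cols = list(tbl.columns)
        if len(cols) >= n - 1:
            # over-parameterized start: pre-rank by univariate |r| with y.
            # Entering n/2 predictors keeps ~n/2 residual df; entering the
            # maximal n-2 would leave df = 1 and meaningless p-values.
            r = tbl.apply(lambda c: abs(np.corrcoef(c, self.y)[0, 1]))
            drop = r.sort_values(ascending=False).index[max(n // 2, 2) :]
            for c in drop:
                trace.append({"removed": c, "reason": "pre-ranking (p >= n)", "value": float(r[c])})
            cols = [c for c in cols if c not in set(drop)]

        # variable selection on coefficient p-values.  Backward elimination
        # drops the single worst predictor per refit; the forced-entry
        # corroboration enters everything and prunes all non-contributing
        # predictors per refit.  Both iterate to a stable set.
        while cols:
            res = self._ols(cols)
            pvals = pd.Series(res.pvalues[1:], index=cols)
            over = pvals[pvals > self.p_threshold]
            if over.empty:
                break
            drop = list(over.index) if self.forced_entry else [pvals.idxmax()]
            for c in drop:
                trace.append({"removed": c, "reason": f"p > {self.p_threshold}", "value": float(pvals[c])})
                cols.remove(c)

        # VIF pruning
        while len(cols) >= 2:
            v = vif(self.features[cols])
            worst = v.idxmax()
            if v[worst] < self.vif_threshold:
                break
            trace.append({"removed": worst, "reason": f"VIF >= {self.vif_threshold}", "value": float(v[worst])})
            cols.remove(worst)
            # re-check p-values after pruning
            while cols:
                res = self._ols(cols)
                pvals = pd.Series(res.pvalues[1:], index=cols)
                w = pvals.idxmax()
                if pvals[w] <= self.p_threshold:
                    break
                trace.append({"removed": w, "reason": f"p > {self.p_threshold}", "value": float(pvals[w])})
                cols.remove(w)

        if not cols:
            warnings.warn("no predictors survive elimination; intercept-only model")
            return PreferenceRegressionResults(
                retained=[],
                params=pd.Series(dtype=float),
                tvalues=pd.Series(dtype=float),
                pvalues=pd.Series(dtype=float),
                fvalue=float("nan"),
                df_model=0,
                df_resid=n - 1,
                f_pvalue=float("nan"),
                rsquared=0.0,
                rsquared_adj=0.0,
                vifs=pd.Series(dtype=float),
                elimination_trace=trace,
                screen_report=screen_report,
            )

        res = self._ols(cols)
        vifs = vif(self.features[cols]) if len(cols) >= 2 else pd.Series({cols[0]: 1.0})
        return PreferenceRegressionResults(
            retained=cols,
            params=pd.Series(res.params[1:], index=cols),
            tvalues=pd.Series(res.tvalues[1:], index=cols),
            pvalues=pd.Series(res.pvalues[1:], index=cols),
            fvalue=float(res.fvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            f_pvalue=float(res.f_pvalue),
            rsquared=float(res.rsquared),
            rsquared_adj=float(res.rsquared_adj),
            vifs=vifs,
            elimination_trace=trace,
            screen_report=screen_report,
        )


# ---------------------------------------------------------------------------
# PLS1 engine


def _pls1(X: np.ndarray, y: np.ndarray, k_max: int):
    """PLS1 (NIPALS) on centered X, y.

    Returns weights W (p, k), scores T (n, k), x-loadings P (p, k),
    y-loadings q (k,).  Components are computed sequentially, so the
    first k columns are exactly the k-component model.
    """
    Xr = X.copy()
    yr = y.astype(float).copy()
    n, p = X.shape
    W = np.zeros((p, k_max))
    T = np.zeros((n, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    k_eff = 0
    for k in range(k_max):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pk = Xr.T @ t / tt
        qk = yr @ t / tt
        Xr -= np.outer(t, pk)
        yr -= qk * t
        W[:, k], T[:, k], P[:, k], q[k] = w, t, pk, qk
        k_eff += 1
    return W[:, :k_eff], T[:, :k_eff], P[:, :k_eff], q[:k_eff]


def _pls1_coef(W, P, q, k: int) -> np.ndarray:
    """Regression coefficients of the k-component model (centered scale)."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    R = Wk @ np.linalg.inv(Pk.T @ Wk)
    return R @ qk


def _loo_errors(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """Leave-one-out squared prediction errors, shape (n, k_max)."""
    n = X.shape[0]
    errs = np.zeros((n, k_max))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, yt = X[tr], y[tr]
        xm, ym = Xt.mean(axis=0), yt.mean()
        W, T, P, q = _pls1(Xt - xm, yt - ym, k_max)
        k_eff = W.shape[1]
        err = np.full(k_max, (y[i] - ym) ** 2)  # 0-component fallback
        for k in range(1, k_eff + 1):
            coef = _pls1_coef(W, P, q, k)
            pred = (X[i] - xm) @ coef + ym
            err[k - 1 :] = (y[i] - pred) ** 2  # rank-deficient folds reuse last
        errs[i] = err
    return errs


def _select_components(errs: np.ndarray) -> int:
    """Smallest component count within one standard error of the minimum
    LOO mean squared prediction error (the one-SE parsimony rule; plain
    argmin systematically overfits the component count)."""
    n = errs.shape[0]
    mse = errs.mean(axis=0)
    best = int(np.argmin(mse))
    se = errs[:, best].std(ddof=1) / np.sqrt(n)
    for k in range(best + 1):
        if mse[k] <= mse[best] + se:
            return k + 1
    return best + 1


# ---------------------------------------------------------------------------
# PLSR results


@dataclass
class PermutationSummary:
    """Null distribution of PLSR percent variance explained.

    Built by shuffling the outcome, re-selecting the component count by
    cross-validation per permutation, and recording the in-sample percent
    variance explained of the selected model.
    """

    n_permutations: int
    null: np.ndarray
    observed: float
    seed: int

    @property
    def mean(self) -> float:
        return float(self.null.mean())

    @property
    def sd(self) -> float:
        return float(self.null.std(ddof=1))

    @property
    def min(self) -> float:
        return float(self.null.min())

    @property
    def max(self) -> float:
        return float(self.null.max())

    @property
    def zscore(self) -> float:
        return float((self.observed - self.mean) / self.sd)

    @property
    def pvalue(self) -> float:
        """Empirical p with the add-one correction (never exactly zero)."""
        return float((1 + np.sum(self.null >= self.observed)) / (1 + self.n_permutations))

    def summary(self) -> str:
        return (
            f"Permutation null ({self.n_permutations} shuffles): "
            f"{self.min:.2f}%..{self.max:.2f}% (M = {self.mean:.2f}, SD = {self.sd:.2f}); "
            f"observed {self.observed:.2f}% (z = {self.zscore:.2f}, p = {self.pvalue:.4g})"
        )


@dataclass
class PLSPreferenceResults:
    """Fitted PLS1 model: chosen components, variance explained, VIPs."""

    n_components: int
    pct_variance_explained: float
    vip: pd.Series
    coef: pd.Series
    signs: pd.Series
    cv_press: np.ndarray
    vip_threshold: float
    model: "PLSPreference"

    @property
    def important(self) -> pd.Series:
        """VIP scores above threshold, descending, with relationship signs."""
        imp = self.vip[self.vip > self.vip_threshold].sort_values(ascending=False)
        return imp

    def summary(self) -> str:
        lines = [
            "Partial least squares regression (PLS1)",
            "=" * 60,
            f"components (LOO CV): {self.n_components}; "
            f"variance explained: {self.pct_variance_explained:.1f}%",
            "-" * 60,
            f"{'predictor':<32}{'VIP':>7}  sign",
        ]
        for c, v in self.important.items():
            lines.append(f"{c:<32}{v:>7.2f}  {'-ve' if self.signs[c] < 0 else '+ve'}")
        return "\n".join(lines)

    def permutation_test(self, n_permutations: int = 10_000, seed: int = 0) -> PermutationSummary:
        return self.model.permutation_null(n_permutations=n_permutations, seed=seed)


class PLSPreference:
    """PLS regression of a preference score on the image-statistics table.

    Components are latent directions maximizing covariance between the
    (z-scored) statistics and the outcome; the count is chosen by
    leave-one-out cross-validation (minimum PRESS).  VIP scores satisfy
    mean(VIP^2) = 1 over features.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        y: pd.Series,
        max_components: int | None = None,
        vip_threshold: float = VIP_THRESHOLD,
        standardize: bool = True,
    ):
        features, y = features.align(y, join="inner", axis=0)
        if features.isna().any().any() or y.isna().any():
            raise ValueError("features/outcome contain missing values")
        if standardize:
            features = zscore(features)
            y = zscore(y)
        n, p = features.shape
        if n < 3:
            raise ValueError("need at least 3 observations")
        self.features = features
        self.y = y
        self.max_components = min(max_components or 10, n - 1, p)
        self.vip_threshold = vip_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, **kw) -> "PLSPreference":
        return cls(df.drop(columns=outcome), df[outcome], **kw)

    # internal: fit on given y vector, return (k, pct_var, W, T, P, q)
    def _fit_vector(self, yv: np.ndarray, select: bool = True):
        X = self.features.to_numpy()
        Xc = X - X.mean(axis=0)
        yc = yv - yv.mean()
        errs = _loo_errors(X, yv, self.max_components)
        press = errs.sum(axis=0)
        k = _select_components(errs) if select else self.max_components
        W, T, P, q = _pls1(Xc, yc, k)
        k = W.shape[1]
        resid = yc - T @ q
        ssy = float(yc @ yc)
        pct = 100.0 * (1.0 - float(resid @ resid) / ssy) if ssy > 0 else 0.0
        return k, pct, W, T, P, q, press

    def fit(self, n_components: int | None = None) -> PLSPreferenceResults:
        yv = self.y.to_numpy(dtype=float)
        if n_components is None:
            k, pct, W, T, P, q, press = self._fit_vector(yv, select=True)
        else:
            X = self.features.to_numpy()
            Xc = X - X.mean(axis=0)
            yc = yv - yv.mean()
            W, T, P, q = _pls1(Xc, yc, n_components)
            k = W.shape[1]
            resid = yc - T @ q
            ssy = float(yc @ yc)
            pct = 100.0 * (1.0 - float(resid @ resid) / ssy)
            press = np.array([])
        if pct <= 0:
            raise ValueError("model explains no outcome variance")
        vip = self._vip(W, T, q)
        coef = _pls1_coef(W, P, q, k)
        cols = self.features.columns
        return PLSPreferenceResults(
            n_components=k,
            pct_variance_explained=pct,
            vip=pd.Series(vip, index=cols, name="VIP"),
            coef=pd.Series(coef, index=cols, name="coef"),
            signs=pd.Series(np.sign(coef), index=cols, name="sign"),
            cv_press=press,
            vip_threshold=self.vip_threshold,
            model=self,
        )

    @staticmethod
    def _vip(W: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Variable importance in projection.

        VIP_j = sqrt(p * sum_k SSY_k w_jk^2 / sum_k SSY_k) with
        SSY_k = q_k^2 t_k't_k the outcome variance captured by component
        k and normalized weights w_k; hence mean(VIP^2) = 1.
        """
        p = W.shape[0]
        ssy = q**2 * np.einsum("ij,ij->j", T, T)
        tot = ssy.sum()
        if tot <= 0:
            raise ValueError("zero explained variance; VIP undefined")
        return np.sqrt(p * (W**2 @ ssy) / tot)

    def permutation_null(self, n_permutations: int = 10_000, seed: int = 0) -> PermutationSummary:
        """Reference distribution of percent variance explained under the
        null of no feature-outcome link.

        Each permutation shuffles the outcome across images, re-selects
        the component count by LOO cross-validation, and records the
        selected model's in-sample percent variance explained.
        """
        if n_permutations < 100:
            warnings.warn("fewer than 100 permutations: unstable null")
        obs = self.fit().pct_variance_explained
        rng = np.random.default_rng(seed)
        yv = self.y.to_numpy(dtype=float)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            yp = rng.permutation(yv)
            _, pct, *_ = self._fit_vector(yp, select=True)
            null[i] = pct
        return PermutationSummary(
            n_permutations=n_permutations, null=null, observed=obs, seed=seed
        )


# ---------------------------------------------------------------------------
# functional wrappers


def backward_eliminate(
    tbl: pd.DataFrame,
    y: pd.Series,
    p_threshold: float = P_THRESHOLD,
    vif_threshold: float = VIF_THRESHOLD,
    screen: bool = False,
) -> PreferenceRegressionResults:
    return PreferenceRegression(
        tbl, y, p_threshold=p_threshold, vif_threshold=vif_threshold, screen=screen
    ).fit()


def fit_mlr(tbl: pd.DataFrame, y: pd.Series) -> PreferenceRegressionResults:
    """Plain OLS (no elimination) of y on all columns of tbl, standardized."""
    model = PreferenceRegression(tbl, y, p_threshold=1.0, vif_threshold=np.inf, screen=False)
    return model.fit()


def plsr_fit(
    tbl: pd.DataFrame,
    y: pd.Series,
    max_components: int | None = None,
    n_components: int | None = None,
) -> PLSPreferenceResults:
    return PLSPreference(tbl, y, max_components=max_components).fit(n_components=n_components)


def permutation_null(
    tbl: pd.DataFrame,
    y: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    max_components: int | None = None,
) -> PermutationSummary:
    return PLSPreference(tbl, y, max_components=max_components).permutation_null(
        n_permutations=n_perm, seed=seed
    )
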