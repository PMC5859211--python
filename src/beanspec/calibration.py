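"""PLS1/MLR calibration with segmented cross-validation and diagnostics.

The regression core is PLS1 computed by NIPALS with X-deflation: for a
centered (n, B) matrix X and centered response y, each component takes

    w = X'y / ||X'y||,   t = Xw,   p = X't / t't,   q = y't / t't,

then deflates X <- X - t p' and y <- y - q t. The regression-coefficient
form beta = W (P'W)^-1 q reproduces the factor-form predictions exactly
and is what gets applied per pixel in chemical mapping and thresholded
in wavelength selection.

Model quality follows the standard chemometric panel: RMSEC on the
calibration fit, RMSECV on pooled held-out predictions from segmented
cross-validation (the pre-treatment chain is refitted inside every
training fold so no fold sees held-out statistics), R-squared as the
squared Pearson correlation of predicted versus measured, the
slope/offset of predicted regressed on measured, and RPD — the ratio of
the reference values' standard deviation to RMSECV, with RPD > 2 the
conventional bar for an excellent calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocessing import PreprocessingChain, parse_chain

__all__ = [
    "PLSModel", "MLRModel", "ModelMetrics",
    "fit_pls", "predict", "cross_validate", "compute_metrics",
    "detect_outliers", "fit_mlr",
]


@dataclass
class ModelMetrics:
    """Calibration/cross-validation metric panel for one model."""

    n_lv: int | None
    r2_cal: float
    rmsec: float
    slope_cal: float
    r2_cv: float
    rmsecv: float
    slope_cv: float
    offset_cv: float
    rpd: float
    n: int
    n_outliers_removed: int = 0
    r2_cal_ssr: float = float("nan")  # 1 - SSE/SST variant, for transparency
    r2_cv_ssr: float = float("nan")

    def as_row(self) -> dict:
        return {
            "LV": self.n_lv, "R2_cal": self.r2_cal, "RMSEC": self.rmsec,
            "slope_cal": self.slope_cal, "R2_cv": self.r2_cv,
            "RMSECV": self.rmsecv, "slope_cv": self.slope_cv,
            "offset_cv": self.offset_cv, "RPD": self.rpd, "n": self.n,
            "outliers_removed": self.n_outliers_removed,
        }


@dataclass
class PLSModel:
    """Fitted PLS1 calibration in both factor and beta form."""

    n_lv: int
    weights: np.ndarray        # W, (B, LV)
    x_loadings: np.ndarray     # P, (B, LV)
    y_loadings: np.ndarray     # q, (LV,)
    x_mean: np.ndarray
    y_mean: float
    beta: np.ndarray           # (B,)
    intercept: float
    wavelengths: np.ndarray | None = None
    chain: PreprocessingChain | None = None
    target: str = ""
    fitted_values: np.ndarray | None = field(default=None, repr=False)

    def scores(self, Xp: np.ndarray) -> np.ndarray:
        """Latent-variable scores T of pre-treated spectra."""
        R = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return (np.asarray(Xp, dtype=float) - self.x_mean) @ R

    def predict_pretreated(self, Xp: np.ndarray) -> np.ndarray:
        Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
        return self.intercept + Xp @ self.beta


@dataclass
class MLRModel:
    """Ordinary least-squares calibration on a (usually reduced) band set."""

    coef: np.ndarray
    intercept: float
    wavelengths: np.ndarray | None = None
    chain: PreprocessingChain | None = None
    target: str = ""
    fitted_values: np.ndarray | None = field(default=None, repr=False)

    # uniform interface with PLSModel
    n_lv = None

    @property
    def beta(self) -> np.ndarray:
        return self.coef

    def predict_pretreated(self, Xp: np.ndarray) -> np.ndarray:
        Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
        return self.intercept + Xp @ self.coef


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data; returns (W, P, q)."""
    n, B = Xc.shape
    W = np.zeros((B, n_lv))
    P = np.zeros((B, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            raise np.linalg.LinAlgError(
                f"X residual orthogonal to y at component {a + 1}; reduce n_lv"
            )
        w /= nw
        t = X @ w
        tt = t @ t
        if tt == 0:
            raise np.linalg.LinAlgError(f"degenerate score vector at component {a + 1}")
        p = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
    return W, P, q


def _beta_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(Xp: np.ndarray, y: np.ndarray, n_lv: int,
            wavelengths: np.ndarray | None = None,
            chain: PreprocessingChain | None = None,
            target: str = "") -> PLSModel:
    """Fit PLS1 by NIPALS on pre-treated spectra ``Xp``.

    ``n_lv`` must not exceed min(n - 1, B); the response must vary.
    Deterministic — PLS1 components are closed-form, with no random
    initialization.
    """
    Xp = np.asarray(Xp, dtype=float)
    y = np.asarray(y, dtype=float)
    n, B = Xp.shape
    if not 1 <= n_lv <= min(n - 1, B):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, B)}], got {n_lv}")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    x_mean = Xp.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(Xp - x_mean, y - y_mean, n_lv)
    beta = _beta_from_factors(W, P, q)
    intercept = y_mean - x_mean @ beta
    model = PLSModel(n_lv, W, P, q, x_mean, y_mean, beta, float(intercept),
                     wavelengths=wavelengths, chain=chain, target=target)
    model.fitted_values = model.predict_pretreated(Xp)
    return model


def predict(model: PLSModel | MLRModel, X_new: np.ndarray,
            wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Predict from raw absorbance spectra; the model's chain is applied.

    If both the model and the caller supply a wavelength axis they must
    match exactly.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if wavelengths is not None and model.wavelengths is not None:
        if (len(wavelengths) != len(model.wavelengths)
                or not np.allclose(wavelengths, model.wavelengths)):
            raise ValueError("wavelength axis does not match the model's")
    if model.wavelengths is not None and X_new.shape[1] != len(model.wavelengths):
        raise ValueError(
            f"expected {len(model.wavelengths)} bands, got {X_new.shape[1]}"
        )
    Xp = model.chain.transform(X_new) if model.chain is not None else X_new
    return model.predict_pretreated(Xp)


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error: sqrt(sum((yhat - y)^2) / n)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def _pearson_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(yhat) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def _slope_offset(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """Least-squares slope/offset of predicted regressed on measured."""
    slope, offset = np.polyfit(y, yhat, 1)
    return float(slope), float(offset)


def compute_metrics(y: np.ndarray, y_cal: np.ndarray, y_cv: np.ndarray,
                    n_lv: int | None = None, n_outliers_removed: int = 0) -> ModelMetrics:
    """Assemble the metric panel from calibration and CV predictions."""
    y = np.asarray(y, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    y_cv = np.asarray(y_cv, dtype=float)
    if not (len(y) == len(y_cal) == len(y_cv)):
        raise ValueError("y, y_cal and y_cv must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 samples for the metric panel")
    rmsec = _rmse(y, y_cal)
    rmsecv = _rmse(y, y_cv)
    slope_cal, _ = _slope_offset(y, y_cal)
    slope_cv, offset_cv = _slope_offset(y, y_cv)
    sd_ref = float(np.std(y, ddof=1))
    sst = float(np.sum((y - y.mean()) ** 2))
    return ModelMetrics(
        n_lv=n_lv,
        r2_cal=_pearson_r2(y, y_cal), rmsec=rmsec, slope_cal=slope_cal,
        r2_cv=_pearson_r2(y, y_cv), rmsecv=rmsecv, slope_cv=slope_cv,
        offset_cv=offset_cv,
        rpd=sd_ref / rmsecv if rmsecv > 0 else float("inf"),
        n=len(y), n_outliers_removed=n_outliers_removed,
        r2_cal_ssr=1.0 - float(np.sum((y - y_cal) ** 2)) / sst,
        r2_cv_ssr=1.0 - float(np.sum((y - y_cv) ** 2)) / sst,
    )


def _segments(n: int, n_segments: int, rng: np.random.Generator,
              leave_one_out: bool = False) -> list[np.ndarray]:
    if leave_one_out:
        return [np.array([i]) for i in range(n)]
    perm = rng.permutation(n)
    return [s for s in np.array_split(perm, n_segments) if s.size]


def _per_lv_betas(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """beta at 1..LV components, reusing the same factor sequence."""
    return [_beta_from_factors(W[:, : a + 1], P[:, : a + 1], q[: a + 1])
            for a in range(q.size)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    chain: PreprocessingChain | str | None = None,
    max_lv: int = 15,
    n_segments: int = 10,
    seed: int = 0,
    method: str = "pls",
    leave_one_out: bool = False,
    wavelengths: np.ndarray | None = None,
    target: str = "",
):
    """Segmented cross-validation; returns (per-LV metrics, best model).

    Rows are split into ``n_segments`` random segments fixed by ``seed``.
    For every fold the pre-treatment chain is refitted on the training
    rows only, a PLS model with the largest feasible number of components
    is fitted, and held-out predictions are pooled per component count.
    The winning complexity minimizes RMSECV, ties resolved toward fewer
    components; the final model is refitted on all rows at that
    complexity. ``method="mlr"`` runs the same machinery with ordinary
    least squares (no complexity dimension; metrics list has one entry).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if isinstance(chain, str) or chain is None:
        chain = parse_chain(chain)
    if leave_one_out:
        n_segments = n
    if not 2 <= n_segments <= n:
        raise ValueError("need n >= n_segments >= 2")
    rng = np.random.default_rng(seed)
    folds = _segments(n, n_segments, rng, leave_one_out)

    min_train = min(n - f.size for f in folds)
    if method == "pls":
        feasible = min(max_lv, min_train - 1, X.shape[1])
        if feasible < max_lv:
            warnings.warn(
                f"max_lv={max_lv} exceeds fold capacity; truncated to {feasible}",
                stacklevel=2,
            )
        max_lv = feasible
        y_cv = np.zeros((max_lv, n))
    else:
        y_cv = np.zeros((1, n))

    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        fold_chain = chain.clone_unfitted().fit(X[train])
        Xtr = fold_chain.transform(X[train])
        Xte = np.atleast_2d(fold_chain.transform(X[test_idx]))
        if method == "pls":
            xm = Xtr.mean(axis=0)
            ym = y[train].mean()
            W, P, q = _nipals_pls1(Xtr - xm, y[train] - ym, max_lv)
            for a, beta in enumerate(_per_lv_betas(W, P, q)):
                y_cv[a, test_idx] = ym + (Xte - xm) @ beta
        else:
            coef, icpt = _ols(Xtr, y[train])
            y_cv[0, test_idx] = icpt + Xte @ coef

    full_chain = chain.clone_unfitted().fit(X)
    Xp = full_chain.transform(X)

    if method == "pls":
        rmsecvs = [_rmse(y, y_cv[a]) for a in range(max_lv)]
        best_a = int(np.argmin(rmsecvs))  # first minimum -> fewer LV on ties
        model = fit_pls(Xp, y, best_a + 1, wavelengths=wavelengths,
                        chain=full_chain, target=target)
        per_lv = []
        for a in range(max_lv):
            m_a = fit_pls(Xp, y, a + 1)
            per_lv.append(compute_metrics(y, m_a.fitted_values, y_cv[a], n_lv=a + 1))
        best_metrics = per_lv[best_a]
    else:
        coef, icpt = _ols(Xp, y)
        model = MLRModel(coef, icpt, wavelengths=wavelengths, chain=full_chain,
                         target=target)
        model.fitted_values = model.predict_pretreated(Xp)
        per_lv = [compute_metrics(y, model.fitted_values, y_cv[0], n_lv=None)]
        best_metrics = per_lv[0]

    model.cv_predictions = y_cv[best_a] if method == "pls" else y_cv[0]
    model.metrics = best_metrics
    return per_lv, model


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([np.ones(len(X)), X])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return sol[1:], float(sol[0])


def fit_mlr(X_subset: np.ndarray, y: np.ndarray,
            wavelengths: np.ndarray | None = None,
            chain: PreprocessingChain | None = None,
            target: str = "") -> MLRModel:
    """Ordinary least squares with intercept on a reduced band set.

    Requires fewer columns than n - 1 and a full-rank design; a
    rank-deficient subset raises, naming the dependent columns.
    """
    X_subset = np.asarray(X_subset, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X_subset.shape
    if p > n - 2:
        raise ValueError(f"{p} bands is too many for {n} samples (need p <= n - 2)")
    A = np.column_stack([np.ones(n), X_subset])
    if np.linalg.matrix_rank(A) < p + 1:
        from scipy.linalg import qr

        _, R, piv = qr(A, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(A.shape) * np.finfo(float).eps
        dep = sorted(piv[np.abs(np.diag(R)) <= tol] - 1)
        raise np.linalg.LinAlgError(
            f"band subset is rank-deficient; collinear columns: {dep}"
        )
    coef, icpt = _ols(X_subset, y)
    model = MLRModel(coef, icpt, wavelengths=wavelengths, chain=chain, target=target)
    model.fitted_values = model.predict_pretreated(X_subset)
    return model


def detect_outliers(model: PLSModel, Xp: np.ndarray, y: np.ndarray,
                    leverage_k: float = 6.0, t2_alpha: float = 0.01,
                    resid_k: float = 4.0) -> np.ndarray:
    """Flag calibration outliers by residual, leverage and Hotelling T2.

    A sample is flagged when any of the following holds: its studentized
    y-residual exceeds ``resid_k`` in absolute value; its leverage
    exceeds ``leverage_k * (LV + 1) / n``; or its Hotelling T2 in the
    score space exceeds the F-based limit at the 1 - ``t2_alpha`` level,
    Sidak-adjusted for the number of samples so ``t2_alpha`` is the
    probability that a clean table produces *any* T2 flag. The defaults
    are deliberately conservative: a well-behaved calibration set should
    pass unflagged, and only gross reference or spectral errors (several
    SD out) should be removed. If more than 20 % of rows are flagged a
    warning is issued and the caller should not auto-remove.
    """
    Xp = np.asarray(Xp, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    A = model.n_lv
    T = model.scores(Xp)
    resid = y - model.predict_pretreated(Xp)

    t_ss = (T ** 2).sum(axis=0)
    h = 1.0 / n + ((T ** 2) / t_ss).sum(axis=1)
    s = np.sqrt((resid ** 2).sum() / max(n - A - 1, 1))
    stud = resid / (s * np.sqrt(np.maximum(1.0 - h, 1e-12)))

    t_var = (T ** 2).sum(axis=0) / (n - 1)
    t2 = ((T ** 2) / t_var).sum(axis=1)
    alpha_per_sample = 1.0 - (1.0 - t2_alpha) ** (1.0 / n)
    f_crit = stats.f.ppf(1.0 - alpha_per_sample, A, n - A)
    t2_limit = A * (n - 1) * (n + 1) / (n * (n - A)) * f_crit

    flags = (np.abs(stud) > resid_k) | (h > leverage_k * (A + 1) / n) | (t2 > t2_limit)
    idx = np.nonzero(flags)[0]
    if idx.size > 0.2 * n:
        warnings.warn(
            f"{idx.size}/{n} samples flagged as outliers (> 20 %); "
            "not removing automatically", stacklevel=2,
        )
    return idx


def remove_outliers_and_refit(X: np.ndarray, y: np.ndarray, chain, max_lv: int,
                              n_segments: int = 10, seed: int = 0,
                              wavelengths: np.ndarray | None = None,
                              target: str = ""):
    """One-pass outlier removal: CV fit, flag, drop, single CV refit.

    Returns (metrics_before, metrics_after, final model, flagged indices).
    """
    per_lv, model = cross_validate(X, y, chain, max_lv, n_segments, seed,
                                   wavelengths=wavelengths, target=target)
    before = model.metrics
    Xp = model.chain.transform(X)
    idx = detect_outliers(model, Xp, y)
    if idx.size == 0 or idx.size > 0.2 * len(y):
        return before, before, model, idx
    keep = np.setdiff1d(np.arange(len(y)), idx)
    _, refit = cross_validate(X[keep], y[keep], model.chain.clone_unfitted(),
                              max_lv, n_segments, seed,
                              wavelengths=wavelengths, target=target)
    refit.metrics.n_outliers_removed = idx.size
    return before, refit.metrics, refit, idx
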