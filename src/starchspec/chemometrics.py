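"""PLS regression (NIPALS), sample splitting and model evaluation.

The regression core is single-response NIPALS PLS: predictors are autoscaled
(zero mean, unit n-1 variance per column, calibration statistics) and the
response centred; latent variables are extracted sequentially with deflation.
The latent-variable count is chosen by k-fold cross-validation (contiguous
blocks after a seeded shuffle), taking the smallest count within numerical
tolerance of the minimum RMSECV.

Samples are split into calibration and prediction sets by the rank-order
(middle-of-triplet) rule: sort by reference value, send the middle sample of
every consecutive triplet to the prediction set. With 96 samples this gives a
64/32 split whose prediction-set range lies inside the calibration range.

Models are scored by Pearson correlation (Rc/Rp), RMSE (RMSEC/RMSEP, g/100 g)
and the residual predictive deviation RPD = SD(y_pred) / RMSEP; RPD > 2 is the
conventional bar for rough-screening use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Split",
    "PLSModel",
    "EvalReport",
    "rank_order_split",
    "pls_fit",
    "pls_predict",
    "select_lv_cv",
    "evaluate",
    "rpd",
]


# ---------------------------------------------------------------------------
# Calibration / prediction split
# ---------------------------------------------------------------------------

@dataclass
class Split:
    calibration_ids: list
    prediction_ids: list


def rank_order_split(y: np.ndarray, ids: list | None = None) -> Split:
    """Sort-and-middle-of-triplet split.

    Samples are sorted ascending by ``y`` (ties keep input order); within each
    full consecutive triplet the middle sample goes to the prediction set and
    the outer two to the calibration set. A trailing partial triplet (1-2
    samples) joins the calibration set. Deterministic; no randomness.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples to form a triplet")
    if ids is None:
        ids = list(range(n))
    if len(ids) != n:
        raise ValueError("ids length does not match y")
    order = np.argsort(y, kind="stable")
    pred_pos = order[1 : 3 * (n // 3) : 3]
    pred_mask = np.zeros(n, dtype=bool)
    pred_mask[pred_pos] = True
    return Split(
        calibration_ids=[ids[i] for i in range(n) if not pred_mask[i]],
        prediction_ids=[ids[i] for i in range(n) if pred_mask[i]],
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model.

    ``coefs_by_lv[:, k-1]`` holds the regression vector (autoscaled predictor
    space) using the first k latent variables, so nested sub-models come for
    free; ``b`` and ``intercept`` expose the chosen-LV model on the raw scale
    via ŷ = y_mean + (x - x_mean) / x_scale · b.
    """

    n_lv: int
    W: np.ndarray = field(repr=False)   # p x A weights
    P: np.ndarray = field(repr=False)   # p x A x-loadings
    q: np.ndarray = field(repr=False)   # A y-loadings
    coefs_by_lv: np.ndarray = field(repr=False)  # p x A
    x_mean: np.ndarray = field(repr=False)
    x_scale: np.ndarray = field(repr=False)
    y_mean: float = 0.0

    @property
    def b(self) -> np.ndarray:
        return self.coefs_by_lv[:, self.n_lv - 1]

    @property
    def intercept(self) -> float:
        return float(self.y_mean - (self.x_mean / self.x_scale) @ self.b)

    @property
    def n_vars(self) -> int:
        return self.W.shape[0]


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1 by NIPALS with sequential deflation.

    Predictors are autoscaled and the response centred internally using the
    calibration data passed here. Extraction stops early (with a warning) if
    the residual covariance vanishes, in which case the effective ``n_lv``
    shrinks accordingly.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")
    max_feasible = min(n - 1, p)
    if n_lv < 1 or n_lv > max_feasible:
        raise ValueError(f"n_lv must be in [1, {max_feasible}] for a {n}x{p} problem")

    Xs, x_mean, x_scale = _autoscale(X)
    y_mean = float(y.mean())
    Xk = Xs.copy()
    yk = y - y_mean

    W = np.zeros((p, n_lv))
    Pl = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    A = 0
    for k in range(n_lv):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            warnings.warn(f"NIPALS stopped after {A} components (residual covariance ~ 0)")
            break
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt < 1e-14:
            warnings.warn(f"NIPALS stopped after {A} components (degenerate scores)")
            break
        pk = Xk.T @ t / tt
        qk = float(yk @ t / tt)
        Xk -= np.outer(t, pk)
        yk = yk - qk * t
        W[:, k], Pl[:, k], q[k] = w, pk, qk
        A += 1
    if A == 0:
        raise ValueError("no PLS component could be extracted (X uncorrelated with y)")
    W, Pl, q = W[:, :A], Pl[:, :A], q[:A]

    # nested coefficient vectors: B_k = W_k (P_k^T W_k)^{-1} q_k
    PtW = Pl.T @ W  # upper-triangular with unit-ish diagonal
    coefs = np.zeros((p, A))
    for k in range(1, A + 1):
        coefs[:, k - 1] = W[:, :k] @ np.linalg.solve(PtW[:k, :k], q[:k])
    return PLSModel(A, W, Pl, q, coefs, x_mean, x_scale, y_mean)


def pls_predict(model: PLSModel, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Predict responses for new predictor rows (raw scale)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if X_new.shape[1] != model.n_vars:
        raise ValueError(f"model expects {model.n_vars} predictors, got {X_new.shape[1]}")
    k = model.n_lv if n_lv is None else n_lv
    if not 1 <= k <= model.coefs_by_lv.shape[1]:
        raise ValueError(f"n_lv must be in [1, {model.coefs_by_lv.shape[1]}]")
    Xs = (X_new - model.x_mean) / model.x_scale
    return model.y_mean + Xs @ model.coefs_by_lv[:, k - 1]


def select_lv_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 15,
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by k-fold cross-validation.

    Folds are contiguous blocks of a seeded shuffle. Returns
    ``(best_lv, rmsecv)`` where ``rmsecv[k-1]`` is the cross-validated RMSE
    with k latent variables; ``best_lv`` follows the one-standard-error
    parsimony rule: the smallest count whose cross-validated MSE lies within
    one standard error of the minimum (a strict argmin walks the flat tail of
    the curve and returns needlessly large models). ``max_lv`` beyond the
    feasible rank is truncated with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n]")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    blocks = np.array_split(idx, folds)

    feasible = min(max_lv, min(n - len(b) for b in blocks) - 1, p)
    if feasible < max_lv:
        warnings.warn(f"max_lv truncated from {max_lv} to {feasible} (rank limit)")
    if feasible < 1:
        raise ValueError("not enough samples per fold to fit even one component")

    sq_err = np.zeros((n, feasible))
    for val in blocks:
        train = np.setdiff1d(idx, val, assume_unique=True)
        model = pls_fit(X[train], y[train], feasible)
        for k in range(1, feasible + 1):
            # if NIPALS stopped early, reuse the largest available model upward
            resid = pls_predict(model, X[val], n_lv=min(k, model.n_lv)) - y[val]
            sq_err[val, k - 1] = resid ** 2
    mse = sq_err.mean(axis=0)
    rmsecv = np.sqrt(mse)
    k_min = int(np.argmin(mse))
    se_min = float(sq_err[:, k_min].std(ddof=1) / np.sqrt(n))
    best_lv = int(np.flatnonzero(mse <= mse[k_min] + se_min)[0]) + 1
    return best_lv, rmsecv


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    Rc: float
    RMSEC: float
    Rp: float
    RMSEP: float
    RPD: float
    n_lv: int
    n_vars: int

    def to_dict(self) -> dict:
        return {
            "Rc": self.Rc,
            "RMSEC": self.RMSEC,
            "Rp": self.Rp,
            "RMSEP": self.RMSEP,
            "RPD": self.RPD,
            "n_lv": self.n_lv,
            "n_vars": self.n_vars,
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        if np.allclose(a, b):
            return 1.0
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rpd(sd_reference: float, rmsep: float) -> float:
    """Residual predictive deviation: prediction-set reference SD (n-1
    denominator) over RMSEP. Reported as +inf for a perfect model."""
    if rmsep == 0:
        return float("inf")
    return sd_reference / rmsep


def evaluate(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
) -> EvalReport:
    """Score a fitted model on its calibration and prediction sets."""
    y_cal = np.asarray(y_cal, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if np.std(y_cal) == 0 or np.std(y_pred) == 0:
        raise ValueError("degenerate reference values (zero variance)")
    yhat_cal = pls_predict(model, X_cal)
    yhat_pred = pls_predict(model, X_pred)
    rmsec = float(np.sqrt(np.mean((yhat_cal - y_cal) ** 2)))
    rmsep = float(np.sqrt(np.mean((yhat_pred - y_pred) ** 2)))
    return EvalReport(
        Rc=_pearson(yhat_cal, y_cal),
        RMSEC=rmsec,
        Rp=_pearson(yhat_pred, y_pred),
        RMSEP=rmsep,
        RPD=rpd(float(np.std(y_pred, ddof=1)), rmsep),
        n_lv=model.n_lv,
        n_vars=model.n_vars,
    )
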