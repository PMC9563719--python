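"""Key-variable selection and spectral-textural data fusion.

Spectral variables are selected by competitive adaptive reweighted sampling
(CARS): over N Monte-Carlo runs, a PLS model is fitted on a random 80% of the
calibration samples, variables are weighted by their normalised absolute
regression coefficients, and an exponentially decreasing function (EDF) forces
the retained set to shrink from all p variables down to 2; the run whose
retained set minimises the k-fold RMSECV wins. Texture variables are selected
by simple Pearson correlation with the reference values (|r| strictly above a
threshold, default 0.3).

Low-level fusion concatenates the full spectral and texture blocks
(428 + 12 = 440 columns); mid-level fusion concatenates only the selected
variables from each block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import pls_fit, select_lv_cv

__all__ = [
    "CARSConfig",
    "CARSResult",
    "SelectionReport",
    "edf_ratio",
    "cars_select",
    "correlation_select",
    "fuse_low",
    "fuse_mid",
]


@dataclass
class CARSConfig:
    """CARS hyperparameters (the canonical defaults of the method)."""

    n_runs: int = 50
    calib_fraction: float = 0.8
    max_lv: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0.0 < self.calib_fraction < 1.0:
            raise ValueError("calib_fraction must be in (0, 1)")
        if self.max_lv < 1 or self.cv_folds < 2:
            raise ValueError("max_lv >= 1 and cv_folds >= 2 required")


@dataclass
class CARSResult:
    selected_indices: np.ndarray
    selected_wavelengths: np.ndarray
    rmsecv_by_run: np.ndarray = field(repr=False)
    retained_count_by_run: np.ndarray = field(repr=False)
    best_run: int = 0

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size

    def eliminated_fraction(self, p_total: int) -> float:
        """Fraction of the original variables discarded by the selection."""
        return (p_total - self.n_selected) / p_total


def edf_ratio(i: int, N: int, p: int) -> float:
    """Exponentially decreasing retention fraction r_i = a e^(-k i).

    The constants are pinned by the boundary conditions r_1 = 1 (all p
    variables in run 1) and r_N = 2/p (two variables in the last run):
    k = ln(p/2) / (N - 1), a = e^k.
    """
    if p <= 2:
        raise ValueError("need p > 2 variables for the EDF schedule")
    if not 1 <= i <= N:
        raise ValueError(f"run index {i} outside [1, {N}]")
    k = math.log(p / 2.0) / (N - 1)
    return math.exp(k) * math.exp(-k * i)


def _weighted_draw_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, size: int
) -> np.ndarray:
    w = weights / weights.sum()
    return rng.choice(items, size=size, replace=False, p=w, shuffle=False)


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    config: CARSConfig | None = None,
    wavelengths: np.ndarray | None = None,
) -> CARSResult:
    """Competitive adaptive reweighted sampling over the columns of X.

    Per run i = 1..N: draw ⌈calib_fraction·n⌉ samples without replacement;
    fit PLS on the currently retained variables; weight each variable by
    w_j = |b_j| / Σ|b| from the regression coefficients (autoscaled space);
    enforced selection keeps the top ⌈edf_ratio(i)·p⌉ variables by weight
    (never fewer than 2), and the adaptive reweighted draw (weighted, without
    replacement, same count) fixes the retained set for the next run; finally
    the retained set's cv_folds-fold RMSECV (latent variables chosen on the
    same grid as elsewhere) is recorded. The retained set with minimum RMSECV
    is returned. Fully deterministic given ``config.seed``.
    """
    config = config or CARSConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("CARS needs at least 10 samples")
    if p < 3:
        raise ValueError("CARS needs at least 3 variables")
    rng = np.random.default_rng(config.seed)
    N = config.n_runs
    m = math.ceil(config.calib_fraction * n)

    retained = np.arange(p)
    rmsecv_by_run = np.zeros(N)
    counts = np.zeros(N, dtype=int)
    sets: list[np.ndarray] = []

    for i in range(1, N + 1):
        target = max(2, math.ceil(edf_ratio(i, N, p) * p))
        if target < retained.size:
            # weights come from a Monte-Carlo PLS fit on the current set
            rows = rng.choice(n, size=m, replace=False, shuffle=False)
            n_lv = min(config.max_lv, m - 1, retained.size)
            model = pls_fit(X[np.ix_(rows, retained)], y[rows], n_lv)
            w = np.abs(model.b)
            w_sum = w.sum()
            w = np.full(retained.size, 1.0 / retained.size) if w_sum == 0 else w / w_sum
            top = retained[np.argsort(w, kind="stable")[::-1][:target]]
            top_w = w[np.searchsorted(retained, np.sort(top))]
            # adaptive reweighted draw fixes the order; set content = top weights
            retained = np.sort(
                _weighted_draw_without_replacement(rng, np.sort(top), top_w, target)
            )
        else:
            rng.choice(n, size=m, replace=False, shuffle=False)  # keep stream aligned
        counts[i - 1] = retained.size
        sets.append(retained.copy())
        _, rmsecv = select_lv_cv(
            X[:, retained], y, max_lv=min(config.max_lv, retained.size),
            folds=config.cv_folds, seed=config.seed,
        )
        rmsecv_by_run[i - 1] = rmsecv.min()

    best = int(np.argmin(rmsecv_by_run))
    selected = sets[best]
    wl = np.asarray(wavelengths)[selected] if wavelengths is not None else np.array([])
    return CARSResult(
        selected_indices=selected,
        selected_wavelengths=wl,
        rmsecv_by_run=rmsecv_by_run,
        retained_count_by_run=counts,
        best_run=best,
    )


# ---------------------------------------------------------------------------
# Texture correlation selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Per-feature Pearson correlations with the reference values and the
    names passing the |r| threshold (strict inequality)."""

    texture_r: pd.Series
    texture_selected: list[str]
    threshold: float = 0.3


def correlation_select(
    T: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    threshold: float = 0.3,
    feature_names: list[str] | None = None,
) -> SelectionReport:
    """Pearson correlation of every texture column with y; select |r| > threshold.

    Constant columns are assigned r = 0 (never selected).
    """
    if isinstance(T, pd.DataFrame):
        names = list(T.columns)
        M = T.to_numpy(float)
    else:
        M = np.atleast_2d(np.asarray(T, dtype=np.float64))
        names = feature_names or [f"var{j}" for j in range(M.shape[1])]
    y = np.asarray(y, dtype=np.float64).ravel()
    if M.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlation selection")
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    Mc = M - M.mean(axis=0)
    sx = np.sqrt((Mc ** 2).sum(axis=0))
    r = np.zeros(M.shape[1])
    ok = (sx > 0) & (sy > 0)
    r[ok] = (Mc[:, ok].T @ yc) / (sx[ok] * sy)
    series = pd.Series(r, index=names)
    selected = [name for name, val in series.items() if abs(val) > threshold]
    return SelectionReport(series, selected, threshold)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse_low(X: pd.DataFrame, T: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of the full spectral and texture blocks."""
    if T.shape[1] == 0:
        return X.copy()
    if X.shape[0] != T.shape[0]:
        raise ValueError(f"row mismatch: spectra {X.shape[0]}, texture {T.shape[0]}")
    if not X.index.equals(T.index):
        raise ValueError("sample ids of the spectral and texture blocks are not aligned")
    return pd.concat([X, T], axis=1)


def fuse_mid(
    X: pd.DataFrame,
    cars: CARSResult,
    T: pd.DataFrame,
    sel: SelectionReport,
) -> pd.DataFrame:
    """Concatenate the CARS-selected spectral columns with the
    correlation-selected texture columns (spectral block first)."""
    if cars.n_selected == 0 and not sel.texture_selected:
        raise ValueError("both selections are empty; nothing to fuse")
    blocks = []
    if cars.n_selected:
        blocks.append(X.iloc[:, cars.selected_indices])
    if sel.texture_selected:
        blocks.append(T[sel.texture_selected])
    fused = pd.concat(blocks, axis=1) if len(blocks) > 1 else blocks[0].copy()
    if fused.shape[0] != X.shape[0]:
        raise ValueError("fused blocks disagree on sample count")
    return fused
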