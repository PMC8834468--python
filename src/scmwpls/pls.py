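"""PLS-1 regression engine.

A deterministic NIPALS implementation for a single response: per factor the
weight vector has the closed form ``w = X^T r / ||X^T r||`` so there is no
iterative inner loop and no random initialization; X is deflated after each
factor.  Fits on identical input are reproducible bit-for-bit.

Centering (columns of X and the response) is recomputed inside every fit —
including every moving-window fit and every cross-validation fold.  No
variance scaling is applied anywhere.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
import numpy as np

from .grid import RegionSet
from .preprocess import PreprocessSpec, mean_center

__all__ = [
    "PLSModel",
    "CVResult",
    "pls1_fit",
    "pls1_predict",
    "ssr",
    "loo_rmsecv",
    "max_lv_for_region",
    "nested_coefficients",
    "save_model",
    "load_model",
]

_DEGENERATE_TOL = 1e-12


def _check_shapes(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x channels)")
    n, h = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} entries but X has {n} rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    if k < 1:
        raise ValueError("number of latent variables must be >= 1")
    if k > min(n - 1, h):
        raise ValueError(
            f"k={k} latent variables infeasible for {n} samples x {h} channels "
            f"(max {min(n - 1, h)})"
        )
    if np.ptp(y) == 0:
        raise ValueError("response y has zero variance")
    return X, y


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """Core NIPALS loop on centered data.

    Returns (W, P, q, residuals) where W and P are h x k, q is length k and
    residuals is n x k (response residual after each factor).  If the
    response is fitted exactly before k factors, the remaining columns
    repeat the converged state (trailing factors contribute nothing).
    """
    n, h = Xc.shape
    Xd = Xc.copy()
    r = yc.copy()
    W = np.zeros((h, k))
    P = np.zeros((h, k))
    q = np.zeros(k)
    residuals = np.zeros((n, k))
    scale = float(np.linalg.norm(Xc.T @ yc)) or 1.0
    for j in range(k):
        w = Xd.T @ r
        wn = np.linalg.norm(w)
        if wn <= _DEGENERATE_TOL * scale:
            residuals[:, j:] = r[:, None]
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _DEGENERATE_TOL**2 * scale:
            residuals[:, j:] = r[:, None]
            break
        p = Xd.T @ t / tt
        W[:, j] = w
        P[:, j] = p
        q[j] = float(r @ t) / tt
        Xd -= np.outer(t, p)
        r = r - q[j] * t
        residuals[:, j] = r
    return W, P, q, residuals


def nested_coefficients(Xc: np.ndarray, yc: np.ndarray, k_max: int) -> np.ndarray:
    """Regression vectors b_k for k = 1..k_max from one NIPALS pass
    (columns of the returned h x k_max matrix)."""
    W, P, q, _ = _nipals(Xc, yc, k_max)
    h = Xc.shape[1]
    B = np.zeros((h, k_max))
    PtW = P.T @ W  # upper triangular with unit-free diagonal
    for k in range(1, k_max + 1):
        sub = PtW[:k, :k]
        if abs(np.linalg.det(sub)) <= np.finfo(float).tiny:
            # degenerate tail: reuse previous coefficients
            B[:, k - 1] = B[:, k - 2] if k > 1 else 0.0
            continue
        B[:, k - 1] = W[:, :k] @ np.linalg.solve(sub, q[:k])
    return B


@dataclass
class PLSModel:
    """Fitted PLS-1 calibration.

    Prediction is ``y_hat = (X - x_mean) @ coefficients + y_mean``.
    """

    n_lv: int
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    rmsec: float
    region_set: RegionSet | None = None
    preprocess: PreprocessSpec | None = None
    n_train: int = 0
    analyte: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.x_mean = np.asarray(self.x_mean, dtype=float).ravel()
        if self.coefficients.shape != self.x_mean.shape:
            raise ValueError("coefficients and x_mean must have equal length")


def pls1_fit(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    region_set: RegionSet | None = None,
    preprocess: PreprocessSpec | None = None,
    analyte: str | None = None,
) -> PLSModel:
    """Fit a k-latent-variable PLS-1 calibration (centering recomputed)."""
    X, y = _check_shapes(X, y, k)
    Xc, yc, x_mean, y_mean = mean_center(X, y)
    B = nested_coefficients(Xc, yc, k)
    b = B[:, k - 1]
    resid = yc - Xc @ b
    rmsec = float(np.sqrt(np.mean(resid**2)))
    return PLSModel(
        n_lv=k,
        coefficients=b,
        x_mean=x_mean,
        y_mean=y_mean,
        rmsec=rmsec,
        region_set=region_set,
        preprocess=preprocess,
        n_train=X.shape[0],
        analyte=analyte,
    )


def pls1_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} channels but the model was trained on "
            f"{model.coefficients.shape[0]}"
        )
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def ssr(X: np.ndarray, y: np.ndarray, k: int) -> float:
    """Sum of squared calibration residues at k latent variables
    (``SSR = n * RMSEC**2``)."""
    model = pls1_fit(X, y, k)
    return float(model.rmsec**2 * np.asarray(X).shape[0])


@dataclass
class CVResult:
    """Leave-one-out cross-validation curve and the chosen dimensionality."""

    rmsecv_by_lv: np.ndarray
    chosen_lv: int

    def __post_init__(self) -> None:
        self.rmsecv_by_lv = np.asarray(self.rmsecv_by_lv, dtype=float)
        if not (1 <= self.chosen_lv <= len(self.rmsecv_by_lv)):
            raise ValueError("chosen_lv outside 1..k_max")


def loo_rmsecv(X: np.ndarray, y: np.ndarray, k_max: int) -> CVResult:
    """Full (leave-one-out) cross-validation over k = 1..k_max.

    Each fold refits on the n-1 remaining samples with centering recomputed
    inside the fold.  The chosen dimensionality is the k minimizing RMSECV
    among those where the curve rises at k+1 (lowest value that "increases
    from the next number"); if the curve is still falling at k_max the
    global argmin (k_max) is returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, h = X.shape
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 samples")
    if k_max < 1 or k_max > min(n - 2, h):
        raise ValueError(
            f"k_max={k_max} infeasible for {n} samples x {h} channels "
            f"(max {min(n - 2, h)})"
        )
    press = np.zeros(k_max)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        Xc, yc, x_mean, y_mean = mean_center(Xi, yi)
        B = nested_coefficients(Xc, yc, k_max)
        preds = (X[i] - x_mean) @ B + y_mean
        press += (preds - y[i]) ** 2
    rmsecv = np.sqrt(press / n)
    # 1-based LV counts k whose successor's RMSECV is strictly larger
    candidates = [k for k in range(1, k_max) if rmsecv[k] > rmsecv[k - 1]]
    if candidates:
        # candidates are 1-based LV counts whose successor increases
        chosen = min(candidates, key=lambda k: (rmsecv[k - 1], k))
    else:
        chosen = int(np.argmin(rmsecv)) + 1
        warnings.warn(
            "RMSECV still decreasing at k_max; choosing the global minimum "
            f"k={chosen}",
            stacklevel=2,
        )
    return CVResult(rmsecv_by_lv=rmsecv, chosen_lv=chosen)


def rmsec_curve(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """Calibration RMSEC for k = 1..k_max from one nested fit."""
    X, y = _check_shapes(X, y, k_max)
    Xc, yc, _, _ = mean_center(X, y)
    _, _, _, residuals = _nipals(Xc, yc, k_max)
    return np.sqrt(np.mean(residuals**2, axis=0))


def max_lv_for_region(
    X: np.ndarray,
    y: np.ndarray,
    k_cap: int = 10,
    rel_improvement: float = 0.02,
) -> int:
    """Maximum sensible model dimensionality for a spectral region.

    The cap is the smallest k at which adding one more latent variable
    improves RMSEC by less than ``rel_improvement`` relatively — the point
    where the calibration error "begins to decrease insignificantly" —
    bounded by ``k_cap``, the region width and n-1.
    """
    X = np.asarray(X, dtype=float)
    n, h = X.shape
    cap = min(k_cap, h, n - 1)
    if cap < 1:
        raise ValueError("region too narrow for even one latent variable")
    if cap == 1:
        return 1
    curve = rmsec_curve(X, y, cap)
    for k in range(1, cap):
        prev, nxt = curve[k - 1], curve[k]
        if prev <= 0 or (prev - nxt) / prev < rel_improvement:
            return k
    return cap


# ------------------------------------------------------------ batched engine

def batched_pls1_ssr(X3: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """Residual sums for many window fits at once.

    X3 is (positions, samples, channels); one PLS-1 model is fitted per
    position on centered data and the sum of squared calibration residues is
    recorded after each factor.  Returns (positions, k_max).  Positions whose
    response is exhausted early keep their converged SSR for larger k
    (trailing factors contribute nothing), so rows are non-increasing in k.
    """
    X3 = np.asarray(X3, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    P, n, w = X3.shape
    if y.shape[0] != n:
        raise ValueError("y length must match X3 sample axis")
    Xd = X3 - X3.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    R = np.broadcast_to(yc, (P, n)).copy()
    ssr_out = np.zeros((P, k_max))
    eps = _DEGENERATE_TOL
    for j in range(k_max):
        W = np.matmul(Xd.transpose(0, 2, 1), R[:, :, None])  # (P, w, 1)
        wn = np.linalg.norm(W, axis=1, keepdims=True)
        W = np.where(wn > eps, W / np.where(wn > 0, wn, 1.0), 0.0)
        T = np.matmul(Xd, W)  # (P, n, 1)
        tt = np.sum(T * T, axis=1, keepdims=True)  # (P, 1, 1)
        safe_tt = np.where(tt > eps**2, tt, 1.0)
        Pl = np.matmul(Xd.transpose(0, 2, 1), T) / safe_tt  # (P, w, 1)
        q = np.sum(R[:, :, None] * T, axis=1, keepdims=True) / safe_tt  # (P,1,1)
        q = np.where(tt > eps**2, q, 0.0)
        Pl = np.where(tt > eps**2, Pl, 0.0)
        Xd -= np.matmul(T, Pl.transpose(0, 2, 1))
        R = R - (q[:, :, 0] * T[:, :, 0])
        ssr_out[:, j] = np.sum(R * R, axis=1)
    return ssr_out


def batched_pls1_rmsec(X3: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Calibration RMSEC per position at exactly k latent variables."""
    n = X3.shape[1]
    return np.sqrt(batched_pls1_ssr(X3, y, k)[:, k - 1] / n)


# ------------------------------------------------------------ serialization

def save_model(model: PLSModel, path: str | os.PathLike) -> None:
    """Write a model as a plain-text JSON file so fitting and prediction can
    run as separate invocations."""
    payload = {
        "n_lv": model.n_lv,
        "coefficients": model.coefficients.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "rmsec": model.rmsec,
        "region_set": str(model.region_set) if model.region_set else None,
        "preprocess": model.preprocess.to_dict() if model.preprocess else None,
        "n_train": model.n_train,
        "analyte": model.analyte,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | os.PathLike) -> PLSModel:
    with open(path) as fh:
        payload = json.load(fh)
    return PLSModel(
        n_lv=payload["n_lv"],
        coefficients=np.array(payload["coefficients"]),
        x_mean=np.array(payload["x_mean"]),
        y_mean=payload["y_mean"],
        rmsec=payload["rmsec"],
        region_set=(
            RegionSet.from_string(payload["region_set"])
            if payload.get("region_set")
            else None
        ),
        preprocess=(
            PreprocessSpec.from_dict(payload["preprocess"])
            if payload.get("preprocess")
            else None
        ),
        n_train=payload.get("n_train", 0),
        analyte=payload.get("analyte"),
    )
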