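"""Calibration/validation statistics and ISO-12099-style acceptance verdicts.

Conventions (x = reference, y = predicted, n = number of predictions):

* ``bias = mean(x - y)``
* ``SEP  = sqrt( sum((x - y - bias)^2) / (n - 1) )``
* ``RMSE = sqrt( sum((x - y)^2) / n )`` — RMSEC on the calibration set,
  RMSEP on the test set
* ``R^2`` — squared product-moment correlation between x and y
* ``RPD  = SD(reference, test set) / RMSEP``
* ``T_b  = t_{1-alpha/2, n-1} * SEP / sqrt(n)`` — bias confidence limit
* ``T_UE = SEC * sqrt(F_{alpha}(nu, M))`` with ``nu = n_p - 1`` and
  ``M = n_c - LVs - 1`` — unexplained-error confidence limit.  The square
  root follows ISO 12099; see docs/methods.md for why the radical is used.

A model is accepted when ``SEP < T_UE`` and ``|bias| < T_b`` (strict).

``n_effective`` for the confidence limits is caller-supplied: when repeated
subsamples share one sampling event, the number of independent events (not
spectra) is the defensible count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "regression_stats",
    "rpd",
    "bias_confidence_limit",
    "unexplained_error_limit",
    "verdict",
    "evaluate_predictions",
]


def regression_stats(
    y_ref: np.ndarray, y_pred: np.ndarray, role: str = "test"
) -> tuple[float, float, float, float]:
    """(R^2, RMSE, SEP, bias) for a reference/prediction pair."""
    x = np.asarray(y_ref, dtype=float).ravel()
    y = np.asarray(y_pred, dtype=float).ravel()
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    if role not in ("calibration", "test"):
        raise ValueError(f"role must be 'calibration' or 'test', got {role!r}")
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("reference values have zero variance; R^2 undefined")
    err = x - y
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    sep = float(np.sqrt(np.sum((err - bias) ** 2) / (n - 1)))
    sy = np.sum((y - y.mean()) ** 2)
    if sy == 0:
        r2 = 0.0
    else:
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        r2 = float(sxy**2 / (np.sum((x - x.mean()) ** 2) * sy))
    return r2, rmse, sep, bias


def rpd(sd_ref_test: float, rmsep: float) -> float:
    """Residual predictive deviation: test-set reference SD over RMSEP."""
    if rmsep <= 0:
        raise ValueError("RMSEP must be positive")
    return sd_ref_test / rmsep


def bias_confidence_limit(sep: float, n_effective: int, alpha: float = 0.05) -> float:
    """Two-sided bias confidence limit T_b = t_{1-alpha/2, n-1} * SEP / sqrt(n)."""
    if n_effective < 2:
        raise ValueError("n_effective must be >= 2")
    if sep < 0:
        raise ValueError("SEP must be non-negative")
    t = stats.t.ppf(1 - alpha / 2, df=n_effective - 1)
    return float(t * sep / np.sqrt(n_effective))


def unexplained_error_limit(
    sec: float, nu: int, M: int, alpha: float = 0.05
) -> float:
    """Unexplained-error confidence limit T_UE = SEC * sqrt(F_alpha(nu, M))."""
    if nu < 1 or M < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if sec < 0:
        raise ValueError("SEC must be non-negative")
    f = stats.f.ppf(1 - alpha, dfn=nu, dfd=M)
    return float(sec * np.sqrt(f))


def verdict(
    sep: float, bias: float, t_ue: float, t_b: float
) -> tuple[str, str]:
    """Accept/reject, separately for unexplained error and bias (strict
    inequalities: equality with a nonzero limit is a rejection).  The
    degenerate perfect fit — error and limit both exactly zero — is
    accepted: a model with no error cannot fail an error criterion."""
    if t_ue < 0 or t_b < 0:
        raise ValueError("confidence limits must be non-negative")
    verdict_sep = "accepted" if sep < t_ue or sep == t_ue == 0 else "rejected"
    verdict_bias = (
        "accepted" if abs(bias) < t_b or abs(bias) == t_b == 0 else "rejected"
    )
    return verdict_sep, verdict_bias


@dataclass
class EvaluationReport:
    """All headline statistics for one calibrated analyte."""

    analyte: str
    lv_used: int
    n_cal: int
    n_test: int
    n_effective: int
    r2: float
    rmsec: float
    rmsep: float
    sep: float
    bias: float
    rpd: float
    t_b: float
    t_ue: float
    verdict_sep: str
    verdict_bias: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def to_text(self) -> str:
        rows = [
            ("analyte", self.analyte),
            ("LVs", self.lv_used),
            ("n (calibration)", self.n_cal),
            ("n (test)", self.n_test),
            ("n (confidence limits)", self.n_effective),
            ("R^2 (test)", f"{self.r2:.4g}"),
            ("RMSEC", f"{self.rmsec:.4g}"),
            ("RMSEP", f"{self.rmsep:.4g}"),
            ("SEP", f"{self.sep:.4g}"),
            ("bias", f"{self.bias:.4g}"),
            ("RPD", f"{self.rpd:.4g}"),
            ("T_b", f"+/-{self.t_b:.4g}"),
            ("T_UE", f"{self.t_ue:.4g}"),
            ("SEP verdict", self.verdict_sep),
            ("bias verdict", self.verdict_bias),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def evaluate_predictions(
    y_cal_ref: np.ndarray,
    y_cal_pred: np.ndarray,
    y_test_ref: np.ndarray,
    y_test_pred: np.ndarray,
    lv_used: int,
    analyte: str = "",
    n_effective: int | None = None,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Full report for one analyte given calibration and test predictions.

    ``n_effective`` defaults to the number of test predictions; pass the
    number of independent sampling events when subsamples are replicated.
    """
    _, rmsec, sec, _ = regression_stats(y_cal_ref, y_cal_pred, "calibration")
    r2, rmsep, sep, bias = regression_stats(y_test_ref, y_test_pred, "test")
    n_cal = len(np.asarray(y_cal_ref).ravel())
    n_test = len(np.asarray(y_test_ref).ravel())
    n_eff = n_test if n_effective is None else n_effective
    sd_test = float(np.std(np.asarray(y_test_ref, dtype=float), ddof=1))
    t_b = bias_confidence_limit(sep, n_eff, alpha)
    nu = n_eff - 1
    M = max(1, n_cal - lv_used - 1)
    t_ue = unexplained_error_limit(sec, nu, M, alpha)
    v_sep, v_bias = verdict(sep, bias, t_ue, t_b)
    return EvaluationReport(
        analyte=analyte,
        lv_used=lv_used,
        n_cal=n_cal,
        n_test=n_test,
        n_effective=n_eff,
        r2=r2,
        rmsec=rmsec,
        rmsep=rmsep,
        sep=sep,
        bias=bias,
        rpd=rpd(sd_test, rmsep) if rmsep > 0 else float("inf"),
        t_b=t_b,
        t_ue=t_ue,
        verdict_sep=v_sep,
        verdict_bias=v_bias,
    )
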