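"""Affinity unit conversions, calibration regressions, and diagnostics.

Implements simple (two-parameter) ordinary least squares with the full
goodness-of-fit suite used by classical calibration reports: R^2, adjusted
R^2, MSE/RMSE, MAPE, Durbin-Watson, Mallows Cp, AIC/SBC in their
``n*ln(SSE/n) + penalty`` forms, Amemiya's prediction criterion, PRESS/Q^2,
the ANOVA table, and per-point influence diagnostics (leverages,
studentized deleted residuals, Cook's distances).  All diagnostics use the
leverage shortcuts; tests cross-check them against explicit delete-one
refits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from ._units import RT_KCALMOL

__all__ = [
    "AffinityRecord",
    "RegressionResult",
    "SeparationReport",
    "ki_to_dg",
    "dg_to_ki",
    "pki_to_ki",
    "ki_to_pki",
    "convert_affinity",
    "fit_ols",
    "gof_suite",
    "anova",
    "outlier_screen",
    "decoy_separation",
    "predict_from_model",
    "REFERENCE_FMAX_KI_COEFFS",
]

#: intercept/slope of the published Fmax -> Ki(nM) calibration line shipped
#: verbatim with the bundled reference dataset (not exactly recoverable from
#: the rounded score tables; ``predict_from_model`` can use either).
REFERENCE_FMAX_KI_COEFFS = (1026.83687658054, -0.281997931877324)

K_PARAMS = 2  # simple regression: intercept + slope


@dataclass
class AffinityRecord:
    """One compound's experimental constant plus computed scores."""

    compound_id: str
    ki: Optional[float] = None  # nM
    pki: Optional[float] = None
    dg_bind: Optional[float] = None  # kcal/mol
    autodock_pki: Optional[float] = None
    vina_pki: Optional[float] = None
    mmpbsa_pki: Optional[float] = None
    mmgbsa_pki: Optional[float] = None
    total_smd_energy: Optional[float] = None  # kcal/mol
    fmax: Optional[float] = None  # pN
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.ki is not None and self.ki <= 0:
            raise ValueError(f"ki must be positive, got {self.ki}")


@dataclass
class SeparationReport:
    min_active_fmax: float
    max_decoy_fmax: float
    margin: float
    fully_separated: bool


@dataclass
class RegressionResult:
    """Simple-OLS fit with goodness-of-fit and per-point diagnostics.

    ``fit_ols`` populates the core fields; ``gof_suite`` completes the
    information-criterion block.  ``perfect_fit`` flags zero-SSE fits whose
    log-based criteria are undefined.
    """

    intercept: float
    slope: float
    n: int
    k: int
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    raw_residuals: np.ndarray
    leverages: np.ndarray
    sse: float
    sst: float
    ssr: float
    r2: float
    f_stat: float
    p_value: float
    studentized_deleted_residuals: np.ndarray
    cooks_distances: np.ndarray
    perfect_fit: bool = False
    # completed by gof_suite
    adj_r2: Optional[float] = None
    mse: Optional[float] = None
    rmse: Optional[float] = None
    mape: Optional[float] = None
    dw: Optional[float] = None
    cp: Optional[float] = None
    aic: Optional[float] = None
    sbc: Optional[float] = None
    pc: Optional[float] = None
    press: Optional[float] = None
    q2: Optional[float] = None


# ---------------------------------------------------------------------------
# unit conversions

def ki_to_dg(ki: float, rt: float = RT_KCALMOL) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant in nM.

    dG = RT * ln(Ki[M]) with RT defaulting to 0.592 kcal/mol.
    """
    if ki <= 0:
        raise ValueError(f"Ki must be positive, got {ki}")
    return rt * math.log(ki * 1e-9)


def dg_to_ki(dg: float, rt: float = RT_KCALMOL) -> float:
    """Inverse of :func:`ki_to_dg`; returns Ki in nM."""
    return math.exp(dg / rt) * 1e9


def ki_to_pki(ki: float) -> float:
    if ki <= 0:
        raise ValueError(f"Ki must be positive, got {ki}")
    return -math.log10(ki * 1e-9)


def pki_to_ki(pki: float) -> float:
    return 10.0 ** (-pki) * 1e9


_CONVERTERS = {
    ("ki_nm", "pki"): ki_to_pki,
    ("pki", "ki_nm"): pki_to_ki,
    ("ki_nm", "dg"): ki_to_dg,
    ("dg", "ki_nm"): dg_to_ki,
    ("pki", "dg"): lambda v: ki_to_dg(pki_to_ki(v)),
    ("dg", "pki"): lambda v: ki_to_pki(dg_to_ki(v)),
}


def convert_affinity(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between 'ki_nm', 'pki' and 'dg' (kcal/mol) representations."""
    if from_unit == to_unit:
        return value
    try:
        fn = _CONVERTERS[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(f"unsupported unit pair {from_unit!r} -> {to_unit!r}") from None
    return fn(value)


# ---------------------------------------------------------------------------
# regression

def fit_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Fit y = intercept + slope*x by least squares with diagnostics.

    Requires n >= 3 and a non-constant predictor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("singular design: constant predictor")

    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    resid = y - fitted

    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = sst - sse
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    perfect = sse <= 1e-14 * max(sst, 1.0)

    lev = 1.0 / n + (x - x.mean()) ** 2 / sxx
    dof = n - K_PARAMS
    mse = sse / dof
    if perfect or mse == 0.0:
        f_stat = float("inf")
        p_value = 0.0
        sdr = np.zeros(n)
        cooks = np.zeros(n)
    else:
        f_stat = (ssr / 1.0) / mse
        p_value = float(_st.f.sf(f_stat, 1, dof))
        # delete-one residual SD via the SSE decomposition shortcut
        with np.errstate(invalid="ignore", divide="ignore"):
            s_i_sq = (sse - resid**2 / (1.0 - lev)) / (dof - 1)
            s_i_sq = np.clip(s_i_sq, 0.0, None)
            sdr = resid / np.sqrt(s_i_sq * (1.0 - lev))
        cooks = resid**2 * lev / (K_PARAMS * mse * (1.0 - lev) ** 2)

    return RegressionResult(
        intercept=intercept,
        slope=slope,
        n=n,
        k=K_PARAMS,
        x=x,
        y=y,
        fitted=fitted,
        raw_residuals=resid,
        leverages=lev,
        sse=sse,
        sst=sst,
        ssr=ssr,
        r2=r2,
        f_stat=f_stat,
        p_value=p_value,
        studentized_deleted_residuals=sdr,
        cooks_distances=cooks,
        perfect_fit=perfect,
    )


def gof_suite(fit: RegressionResult) -> RegressionResult:
    """Complete the goodness-of-fit block of a fitted model.

    AIC and SBC use the ``n*ln(SSE/n) + penalty`` forms; PC is Amemiya's
    prediction criterion ``(1-R^2)(n+k)/(n-k)``; Cp is reported as k for the
    (degenerate) case where the candidate model is the full model.
    """
    n, k = fit.n, fit.k
    if n <= k:
        raise ValueError(f"need n > k for goodness of fit, n={n}, k={k}")
    resid = fit.raw_residuals
    mse = fit.sse / (n - k)
    adj_r2 = 1.0 - (1.0 - fit.r2) * (n - 1) / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        mape = float(100.0 / n * np.sum(np.abs(resid / fit.y)))
    denom = float(np.sum(resid**2))
    dw = float(np.sum(np.diff(resid) ** 2) / denom) if denom > 0 else float("nan")
    press = float(np.sum((resid / (1.0 - fit.leverages)) ** 2))
    q2 = 1.0 - press / fit.sst if fit.sst > 0 else float("nan")
    if fit.perfect_fit:
        aic = sbc = float("-inf")
    else:
        aic = n * math.log(fit.sse / n) + 2 * k
        sbc = n * math.log(fit.sse / n) + k * math.log(n)
    pc = (1.0 - fit.r2) * (n + k) / (n - k)
    return replace(
        fit,
        adj_r2=adj_r2,
        mse=mse,
        rmse=math.sqrt(mse),
        mape=mape,
        dw=dw,
        cp=float(k),
        aic=aic,
        sbc=sbc,
        pc=pc,
        press=press,
        q2=q2,
    )


def anova(fit: RegressionResult) -> pd.DataFrame:
    """ANOVA table (Model / Error / Corrected Total) for a simple fit."""
    if fit.n < 4:
        raise ValueError("ANOVA requires n >= 4")
    n = fit.n
    dof_err = n - fit.k
    mse = fit.sse / dof_err
    f = float("inf") if fit.perfect_fit else fit.f_stat
    p = 0.0 if fit.perfect_fit else fit.p_value
    return pd.DataFrame(
        {
            "DF": [1, dof_err, n - 1],
            "Sum of Squares": [fit.ssr, fit.sse, fit.sst],
            "Mean Squares": [fit.ssr / 1.0, mse, np.nan],
            "F": [f, np.nan, np.nan],
            "Pr > F": [p, np.nan, np.nan],
        },
        index=["Model", "Error", "Corrected Total"],
    )


def outlier_screen(
    fit: RegressionResult,
    sdr_threshold: float = 3.0,
    cook_threshold: float = 1.0,
) -> np.ndarray:
    """Boolean outlier flags: |SDR| > sdr_threshold or Cook's D > cook_threshold."""
    if fit.n <= fit.k + 1:
        raise ValueError(f"need n > k+1 for outlier screening, n={fit.n}")
    return (np.abs(fit.studentized_deleted_residuals) > sdr_threshold) | (
        fit.cooks_distances > cook_threshold
    )


def decoy_separation(
    actives: Sequence[float], decoys: Sequence[float]
) -> SeparationReport:
    """Margin between the weakest active and the strongest decoy Fmax."""
    actives = np.asarray(actives, dtype=float)
    decoys = np.asarray(decoys, dtype=float)
    if actives.size == 0 or decoys.size == 0:
        raise ValueError("actives and decoys must both be non-empty")
    lo = float(actives.min())
    hi = float(decoys.max())
    margin = lo - hi
    return SeparationReport(
        min_active_fmax=lo,
        max_decoy_fmax=hi,
        margin=margin,
        fully_separated=margin > 0,
    )


def predict_from_model(fit: RegressionResult, x_new):
    """Predict the response at x_new from a fitted line."""
    return fit.intercept + fit.slope * np.asarray(x_new, dtype=float)
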