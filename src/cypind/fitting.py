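"""Sigmoidal Hill 4-parameter dose-response fitting.

The model is y = E_min + (E_max − E_min) / (1 + (EC50/x)^b) on the
fold-increase scale. Fits use multi-start bounded nonlinear least squares;
a fit is accepted only when R² > 0.85. Data sets with no apparent plateau
keep the observed maximum fold increase as E_max (to avoid extrapolating
far above the tested range) and EC50 is re-derived from the curve refitted
under that constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import FitError
from .induction import FoldIncreasePoint


def hill4(
    x: float | np.ndarray,
    e_min: float,
    e_max: float,
    ec50: float,
    b: float,
) -> float | np.ndarray:
    """Hill 4-parameter response at concentration x (µM)."""
    x = np.asarray(x, dtype=float)
    out = e_min + (e_max - e_min) / (1.0 + (ec50 / x) ** b)
    return float(out) if out.ndim == 0 else out


class FitMethod(str, Enum):
    FULL_FIT = "full_fit"
    OBSERVED_MAX_FALLBACK = "observed_max_fallback"


@dataclass(frozen=True)
class InductionCurveFit:
    e_min: float
    e_max: float
    ec50: float
    slope_b: float
    r_squared: float
    method: FitMethod
    n_points_used: int
    accepted: bool

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return hill4(x, self.e_min, self.e_max, self.ec50, self.slope_b)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _multistart_ls(residual, starts, lower, upper):
    best = None
    for x0 in starts:
        x0c = np.clip(x0, lower, upper)
        try:
            sol = least_squares(residual, x0c, bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("Hill fit failed to converge from every start")
    return best


def fit_hill4(
    points: Sequence[FoldIncreasePoint],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> InductionCurveFit:
    """Fit the Hill-4 model to accepted fold-increase points.

    Multi-start strategy: slope starts at {0.5, 1, 2, 4}; EC50 starts at
    the geometric mean and log-quartiles of the tested range; E_max starts
    at the observed maximum; E_min at 0. Bounds keep E_min within the
    observed range, E_max below 5× the observed maximum, the slope in
    (0.1, 10] and EC50 within two decades of the tested range.
    """
    acc = [p for p in points if p.accepted]
    if len(acc) < 4:
        raise FitError(f"need ≥4 accepted points, got {len(acc)}")
    x = np.array([p.concentration for p in acc], dtype=float)
    y = np.array([p.fold_increase for p in acc], dtype=float)
    if np.ptp(y) == 0:
        raise FitError("degenerate response: all fold increases equal")
    obs_max = float(y.max())
    if obs_max <= 0:
        raise FitError("no positive fold increase to fit")

    lx = np.log10(x)
    ec50_starts = 10.0 ** np.quantile(lx, [0.25, 0.5, 0.75])
    lower = np.array([0.0, 1e-9, x.min() / 100.0, 0.1])
    upper = np.array([obs_max, 5.0 * obs_max, x.max() * 100.0, 10.0])

    def residual(theta):
        e_min, e_max, ec50, b = theta
        return hill4(x, e_min, e_max, ec50, b) - y

    starts = [
        np.array([0.0, obs_max, c0, b0])
        for b0 in (0.5, 1.0, 2.0, 4.0)
        for c0 in ec50_starts
    ]
    sol = _multistart_ls(residual, starts, lower, upper)
    e_min, e_max, ec50, b = sol.x
    r2 = _r_squared(y, hill4(x, *sol.x))

    # Plateau check: the fitted E_max must stay close to the observed
    # maximum and the top tested concentration must be near the plateau.
    top_resp = hill4(x.max(), *sol.x)
    has_plateau = (
        e_max <= config.plateau_emax_ratio * obs_max
        and top_resp >= config.plateau_top_fraction * e_max
    )
    method = FitMethod.FULL_FIT
    if not has_plateau:
        # No apparent plateau: keep observed max as E_max, refit the rest.
        method = FitMethod.OBSERVED_MAX_FALLBACK

        def residual_fixed(theta):
            e_min_, ec50_, b_ = theta
            return hill4(x, e_min_, obs_max, ec50_, b_) - y

        starts_fixed = [
            np.array([0.0, c0, b0]) for b0 in (0.5, 1.0, 2.0, 4.0) for c0 in ec50_starts
        ]
        sol2 = _multistart_ls(
            residual_fixed, starts_fixed,
            np.array([0.0, x.min() / 100.0, 0.1]),
            np.array([obs_max, x.max() * 100.0, 10.0]),
        )
        e_min, ec50, b = sol2.x
        e_max = obs_max
        r2 = _r_squared(y, hill4(x, e_min, e_max, ec50, b))

    return InductionCurveFit(
        e_min=float(e_min),
        e_max=float(e_max),
        ec50=float(ec50),
        slope_b=float(b),
        r_squared=float(r2),
        method=method,
        n_points_used=len(acc),
        accepted=bool(r2 > config.r2_min),
    )


@dataclass(frozen=True)
class CompoundLotResult:
    """Fit outcome for one compound × lot: a fit, or an NI/NA sentinel.

    status "fit": a numeric Hill fit; "na": responder without concentration
    dependence (only the observed maximum fold induction is reported);
    "ni": no induction observed.
    """

    status: str  # fit | na | ni
    fit: InductionCurveFit | None = None
    max_fold_induction: float | None = None


def collect_fit_table(results: dict[tuple[str, str], CompoundLotResult]) -> pd.DataFrame:
    """Summary table, one row per compound, R²/E_max/EC50 columns per lot.

    Non-inducers print NI; concentration-independent responders print NA
    with their observed maximum fold induction in the E_max column.
    """
    compounds = sorted({c for c, _ in results})
    lots = sorted({l for _, l in results})
    rows = []
    for compound in compounds:
        row: dict[str, object] = {"compound": compound}
        for lot in lots:
            res = results.get((compound, lot))
            if res is None or res.status == "ni":
                r2, emax, ec50 = "NI", "NI", "NI"
            elif res.status == "na":
                r2, ec50 = "NA", "NA"
                emax = f"{res.max_fold_induction:g}" if res.max_fold_induction is not None else "NA"
            else:
                assert res.fit is not None
                r2 = f"{res.fit.r_squared:.2f}"
                emax = f"{res.fit.e_max:.3g}"
                ec50 = f"{res.fit.ec50:.3g}"
            row[f"{lot}_r2"] = r2
            row[f"{lot}_emax"] = emax
            row[f"{lot}_ec50"] = ec50
        rows.append(row)
    return pd.DataFrame(rows)
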