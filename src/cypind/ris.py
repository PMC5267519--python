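"""Relative induction score (RIS) and its clinical calibration.

RIS = E_max · C_max,ub / (EC50 + C_max,ub) weights in vitro induction
potency by the inducer's unbound clinical exposure. Plotting RIS against
the observed % decrease in midazolam AUC for a calibration set of
compounds and fitting a Hill 3-parameter curve f = a·x^b/(c^b + x^b)
yields a lot-specific model that predicts the clinical AUC change of new
compounds and, inverted at a 20% AUC change, the RIS cutoff separating
clinically relevant inducers from non-inducers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigurationError, DataError, FitError
from .fitting import InductionCurveFit, _multistart_ls, _r_squared


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    observed_auc_change: float | None = None  # percent; negative = AUC increase
    cmax_ub: float | None = None  # µM
    substrate_class: Literal["midazolam", "nonmidazolam"] | None = None
    in_calibration_set: bool = False
    category: Literal["strong", "moderate_weak", "noninducer"] | None = None

    def __post_init__(self) -> None:
        if self.cmax_ub is not None and self.cmax_ub <= 0:
            raise DataError(f"{self.name}: cmax_ub must be positive")
        if self.in_calibration_set and self.substrate_class != "midazolam":
            raise DataError(f"{self.name}: calibration compounds must be midazolam studies")


@dataclass(frozen=True)
class RISValue:
    compound: str
    lot: str
    endpoint: str
    ris: float


@dataclass(frozen=True)
class CalibrationModel:
    """Hill-3 calibration: predicted %AUC change = a·x^b/(c^b + x^b)."""

    a: float  # maximum AUC change, percent
    b_slope: float
    c: float  # RIS at half-maximal AUC change
    r_squared: float = float("nan")
    lot: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b_slope <= 0 or self.c <= 0:
            raise ConfigurationError("calibration parameters a, b, c must be positive")

    def predict(self, ris: float | np.ndarray) -> float | np.ndarray:
        """Predicted % AUC change at a given RIS (0 at RIS 0)."""
        x = np.asarray(ris, dtype=float)
        if np.any(x < 0):
            raise DataError("RIS must be nonnegative")
        with np.errstate(divide="ignore"):
            out = np.where(x > 0, self.a * x**self.b_slope / (self.c**self.b_slope + x**self.b_slope), 0.0)
        return float(out) if out.ndim == 0 else out

    def invert(self, auc_change_pct: float) -> float:
        """RIS producing the given predicted % AUC change (closed form)."""
        t = auc_change_pct
        if not 0 < t < self.a:
            raise ConfigurationError(
                f"threshold {t}% outside the curve's range (0, {self.a:.3g})"
            )
        return float(self.c * (t / (self.a - t)) ** (1.0 / self.b_slope))


def compute_ris(fit: InductionCurveFit, cmax_ub: float, compound: str = "", lot: str = "", endpoint: str = "") -> RISValue:
    """RIS from an accepted curve fit and the unbound clinical C_max."""
    if cmax_ub is None or not cmax_ub > 0:
        raise DataError(f"missing or nonpositive unbound C_max for compound {compound or '?'}")
    ris = fit.e_max * cmax_ub / (fit.ec50 + cmax_ub)
    return RISValue(compound=compound, lot=lot, endpoint=endpoint, ris=float(ris))


def summarize_ris(values: Sequence[RISValue]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cross-lot RIS summary per compound × endpoint.

    Returns a table with the arithmetic mean and the %CV (sample SD over
    mean × 100) across lots, and the grand mean %CV per endpoint (the mean
    of per-compound %CV values).
    """
    df = pd.DataFrame([v.__dict__ for v in values])
    rows = []
    for (compound, endpoint), grp in df.groupby(["compound", "endpoint"], sort=True):
        if grp["lot"].nunique() < 2:
            raise DataError(f"{compound}/{endpoint}: need ≥2 lots for a cross-lot summary")
        vals = grp["ris"].to_numpy(dtype=float)
        mean = vals.mean()
        cv_pct = float(vals.std(ddof=1) / mean * 100.0)
        rows.append({"compound": compound, "endpoint": endpoint, "n_lots": len(vals),
                     "mean_ris": float(mean), "cv_pct": cv_pct})
    summary = pd.DataFrame(rows)
    grand = {
        str(ep): float(sub["cv_pct"].mean())
        for ep, sub in summary.groupby("endpoint")
    }
    return summary, grand


def fit_calibration(
    ris: Sequence[float],
    observed_auc_change: Sequence[float],
    lot: str = "",
    endpoint: str = "",
) -> CalibrationModel:
    """Fit the Hill-3 calibration to (RIS, observed % midazolam AUC change).

    Multi-start bounded least squares on the untransformed pairs: a starts
    at the maximum observed AUC change, c at the median and log-quartiles
    of the RIS values, slope at {1, 2, 4}; bounds a ∈ (20, 120],
    b ∈ (0.1, 10], c > 0.
    """
    x = np.asarray(ris, dtype=float)
    y = np.asarray(observed_auc_change, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("ris and observed AUC change must be equal-length vectors")
    if len(x) < 4:
        raise ConfigurationError(f"need ≥4 calibration points, got {len(x)}")
    if np.any(x <= 0):
        raise DataError("calibration RIS values must be positive")
    if np.any(y <= 0):
        raise DataError("calibration observed AUC changes must be positive")

    def model(theta, xv):
        a, b, c = theta
        return a * xv**b / (c**b + xv**b)

    def residual(theta):
        return model(theta, x) - y

    c_starts = np.quantile(x, [0.25, 0.5, 0.75])
    starts = [np.array([y.max(), b0, c0]) for b0 in (1.0, 2.0, 4.0) for c0 in c_starts]
    lower = np.array([20.0 + 1e-9, 0.1, 1e-12])
    upper = np.array([120.0, 10.0, np.inf])
    try:
        sol = _multistart_ls(residual, starts, lower, upper)
    except FitError as exc:
        raise FitError(f"calibration fit failed for lot={lot} endpoint={endpoint}: {exc}") from exc
    a, b, c = sol.x
    r2 = _r_squared(y, model(sol.x, x))
    return CalibrationModel(a=float(a), b_slope=float(b), c=float(c),
                            r_squared=float(r2), lot=lot, endpoint=endpoint)


def predict_auc_change(model: CalibrationModel, ris: float | None) -> float:
    """Predicted % AUC change; compounds without a RIS predict 0."""
    if ris is None:
        return 0.0
    if ris < 0:
        raise DataError("RIS must be nonnegative")
    return float(model.predict(ris))


def ris_cutoff(model: CalibrationModel, auc_threshold: float = 20.0) -> float:
    """RIS whose predicted AUC change equals the threshold (default 20%)."""
    return model.invert(auc_threshold)


def summarize_cutoffs(models: Sequence[CalibrationModel], auc_threshold: float = 20.0) -> pd.DataFrame:
    """Per-lot cutoffs plus their cross-lot mean and %CV, per endpoint."""
    rows = [
        {"lot": m.lot, "endpoint": m.endpoint, "cutoff": ris_cutoff(m, auc_threshold)}
        for m in models
    ]
    df = pd.DataFrame(rows)
    out = []
    for ep, sub in df.groupby("endpoint", sort=True):
        cuts = sub["cutoff"].to_numpy()
        for _, r in sub.iterrows():
            out.append({"endpoint": ep, "lot": r["lot"], "cutoff": float(r["cutoff"])})
        out.append({
            "endpoint": ep, "lot": "mean", "cutoff": float(cuts.mean()),
            "cv_pct": float(cuts.std(ddof=1) / cuts.mean() * 100.0) if len(cuts) > 1 else float("nan"),
        })
    return pd.DataFrame(out)
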