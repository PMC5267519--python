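"""Prediction accuracy and bias metrics.

RMSE is computed on the fractional AUC-change scale (percent / 100);
GMFE = 10^(mean |log10(predicted/observed)|) measures fold accuracy
irrespective of direction. Reports are stratified by the victim substrate
used in the underlying clinical study, because a calibration built on
midazolam studies transfers poorly to non-midazolam victims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DataError
from .ris import CompoundRecord


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


def rmse(predicted_pct: Sequence[float], observed_pct: Sequence[float]) -> float:
    """Root mean square error on the fractional scale."""
    p = np.asarray(predicted_pct, dtype=float) / 100.0
    o = np.asarray(observed_pct, dtype=float) / 100.0
    if p.shape != o.shape or p.ndim != 1:
        raise DataError("predicted and observed must be equal-length vectors")
    if len(p) == 0:
        raise DataError("empty input to rmse")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def gmfe(
    predicted_pct: Sequence[float],
    observed_pct: Sequence[float],
    return_exclusions: bool = False,
):
    """Geometric mean fold error over pairs with positive predicted and observed.

    Pairs where either value is nonpositive carry no defined fold error and
    are excluded (optionally returned for the audit log).
    """
    p = np.asarray(predicted_pct, dtype=float)
    o = np.asarray(observed_pct, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise DataError("predicted and observed must be equal-length vectors")
    keep = (p > 0) & (o > 0)
    excluded = [
        {"index": int(i), "predicted": float(p[i]), "observed": float(o[i]),
         "reason": "nonpositive predicted" if p[i] <= 0 else "nonpositive observed"}
        for i in np.flatnonzero(~keep)
    ]
    if not keep.any():
        raise DataError(f"no valid pairs for GMFE; exclusions: {excluded}")
    value = float(10.0 ** np.mean(np.abs(np.log10(p[keep] / o[keep]))))
    if return_exclusions:
        return value, excluded
    return value


@dataclass(frozen=True)
class AccuracyReport:
    lot: str
    endpoint: str
    subset: str  # all | midazolam | nonmidazolam
    rmse: float
    gmfe: float | None
    n_compounds: int
    excluded: tuple = field(default_factory=tuple)


def stratified_report(
    predictions: dict[str, float],
    compounds: Sequence[CompoundRecord],
    lot: str,
    endpoint: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[AccuracyReport]:
    """Accuracy reports for the full set and the substrate-class subsets.

    ``predictions`` maps compound name → predicted % AUC change. The
    midazolam subset is the calibration compounds; the non-midazolam subset
    drops the configured exclusions (by default clotrimazole, which has no
    activity-based RIS).
    """
    by_name = {c.name: c for c in compounds}
    missing = [n for n in by_name if by_name[n].observed_auc_change is not None and n not in predictions]
    if missing:
        raise DataError(f"missing predictions for: {sorted(missing)}")

    def subset_names(which: str) -> list[str]:
        names = []
        for c in compounds:
            if c.observed_auc_change is None:
                continue
            if which == "midazolam" and c.substrate_class != "midazolam":
                continue
            if which == "nonmidazolam":
                if c.substrate_class != "nonmidazolam" or c.name in config.nonmidazolam_exclude:
                    continue
            if which == "all" and c.name in config.nonmidazolam_exclude:
                continue
            names.append(c.name)
        return names

    reports = []
    for which in ("all", "midazolam", "nonmidazolam"):
        names = subset_names(which)
        if not names:
            continue
        pred = [predictions[n] for n in names]
        obs = [by_name[n].observed_auc_change for n in names]
        try:
            g, excl = gmfe(pred, obs, return_exclusions=True)
            excluded = tuple(
                {**e, "compound": names[e["index"]]} for e in excl
            )
        except DataError:
            g, excluded = None, tuple()
        reports.append(
            AccuracyReport(
                lot=lot, endpoint=endpoint, subset=which,
                rmse=rmse(pred, obs), gmfe=g,
                n_compounds=len(names), excluded=excluded,
            )
        )
    return reports
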