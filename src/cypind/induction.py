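"""Fold-induction computation and replicate quality control.

Raw replicate measurements (enzyme activity, or qPCR ΔΔCT for mRNA) are
normalized to the solvent vehicle control to give fold induction; fold
increase is fold induction minus 1 and is the quantity fitted downstream.
Points are accepted for curve fitting only when the replicates agree to
within a coefficient of variation below the configured threshold (default
40%), and points flagged as toxic or insoluble upstream are excluded with
their reason preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DataError

Endpoint = Literal["activity", "mrna"]


class ExclusionReason(str, Enum):
    NONE = "none"
    CV = "cv"
    TOXICITY = "toxicity"
    INSOLUBILITY = "insolubility"


class Verdict(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ConcentrationSeries:
    """Replicate measurements for one compound × lot × endpoint.

    For the activity endpoint, ``points`` holds raw activity replicates and
    ``vehicle`` the vehicle-control replicates. For the mRNA endpoint,
    ``points`` holds per-replicate ΔΔCT values (already referenced to the
    vehicle ΔCT) and ``vehicle`` is empty or holds vehicle ΔΔCT replicates.
    """

    compound: str
    lot: str
    endpoint: Endpoint
    points: tuple[tuple[float, tuple[float, ...]], ...]
    vehicle: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(c <= 0 for c in concs):
            raise DataError(f"{self.compound}/{self.lot}: concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise DataError(f"{self.compound}/{self.lot}: duplicate concentrations")
        for c, reps in self.points:
            if len(reps) < 2:
                raise DataError(f"{self.compound}/{self.lot}: <2 replicates at {c} µM")


@dataclass(frozen=True)
class FoldIncreasePoint:
    concentration: float
    fold_induction: float
    replicate_cv: float
    accepted: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def fold_increase(self) -> float:
        return self.fold_induction - 1.0


def fold_induction_activity(treated: Sequence[float], vehicle: Sequence[float]) -> float:
    """Mean treated activity over mean vehicle activity."""
    vmean = float(np.mean(vehicle))
    if vmean <= 0:
        raise DataError(f"vehicle mean must be positive, got {vmean}")
    return float(np.mean(treated)) / vmean


def fold_induction_mrna(ddct: float) -> float:
    """Relative mRNA quantity from ΔΔCT: 2^(−ΔΔCT)."""
    if not math.isfinite(ddct):
        raise DataError(f"ΔΔCT must be finite, got {ddct}")
    return 2.0 ** (-ddct)


def replicate_cv(values: Sequence[float]) -> float:
    """Sample (n−1) standard deviation over the mean of raw replicates."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return math.inf
    return float(arr.std(ddof=1) / abs(mean))


def apply_replicate_qc(
    points: Iterable[FoldIncreasePoint],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[FoldIncreasePoint]:
    """Flag points whose replicate CV is at or above the threshold.

    Points already carrying a toxicity/insolubility reason stay excluded
    with that reason; the CV rule never un-excludes a point.
    """
    out = []
    for p in points:
        if p.exclusion_reason not in (ExclusionReason.NONE, ExclusionReason.CV):
            out.append(replace(p, accepted=False))
        elif p.replicate_cv >= config.cv_threshold:
            out.append(replace(p, accepted=False, exclusion_reason=ExclusionReason.CV))
        else:
            out.append(replace(p, accepted=True, exclusion_reason=ExclusionReason.NONE))
    return out


def fold_increase_points(
    series: ConcentrationSeries,
    config: PipelineConfig = DEFAULT_CONFIG,
    exclusions: dict[float, str] | None = None,
) -> list[FoldIncreasePoint]:
    """Turn a raw series into QC-flagged fold-increase points.

    ``exclusions`` maps concentration → reason ("toxicity"/"insolubility")
    for points ruled out upstream of the CV filter.
    """
    exclusions = exclusions or {}
    pts = []
    for conc, reps in sorted(series.points):
        if series.endpoint == "activity":
            fi = fold_induction_activity(reps, series.vehicle)
            cv = replicate_cv(reps)
        else:
            linear = [fold_induction_mrna(d) for d in reps]
            # geometric-mean fold induction; CV taken on the linear scale,
            # where the multiplicative replicate noise lives
            fi = fold_induction_mrna(float(np.mean(reps)))
            cv = replicate_cv(linear)
        reason = ExclusionReason(exclusions.get(conc, "none"))
        pts.append(FoldIncreasePoint(conc, fi, cv, accepted=False, exclusion_reason=reason))
    return apply_replicate_qc(pts, config)


def is_concentration_dependent(
    points: Sequence[FoldIncreasePoint],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> bool:
    """Operational concentration-dependence call.

    Requires at least ``min_accepted_points`` accepted points, a positive
    Spearman rank correlation between concentration and fold increase, and
    the maximum response occurring above the lowest tested concentration.
    """
    acc = [p for p in points if p.accepted]
    if len(acc) < config.min_accepted_points:
        return False
    conc = [p.concentration for p in acc]
    resp = [max(p.fold_increase, 0.0) for p in acc]
    if len(set(resp)) == 1:
        return False
    rho = stats.spearmanr(conc, resp).statistic
    peak_at = conc[int(np.argmax(resp))]
    return bool(rho > 0 and peak_at > min(conc))


@dataclass(frozen=True)
class InductionCall:
    activity: Verdict
    mrna: Verdict
    combined: Verdict
    fit_eligible: dict[str, bool] = field(default_factory=dict)


def _endpoint_verdict(points: Sequence[FoldIncreasePoint], config: PipelineConfig) -> Verdict:
    acc = [p for p in points if p.accepted]
    if not acc:
        return Verdict.INDETERMINATE
    max_fi = max(p.fold_induction for p in acc)
    if max_fi > config.positive_threshold and is_concentration_dependent(points, config):
        return Verdict.POSITIVE
    return Verdict.NEGATIVE


def classify_induction(
    activity_points: Sequence[FoldIncreasePoint],
    mrna_points: Sequence[FoldIncreasePoint],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> InductionCall:
    """Per-endpoint and combined induction verdicts.

    Positive requires >2-fold induction with a concentration-dependent
    pattern on both endpoints; one positive endpoint gives indeterminate
    (e.g. an mRNA-only responder whose activity signal is masked by
    concurrent enzyme inhibition). Fit eligibility (for EC50/E_max) asks
    only for concentration dependence with maximum response above the
    1.4-fold floor.
    """

    def eligible(points: Sequence[FoldIncreasePoint]) -> bool:
        acc = [p for p in points if p.accepted]
        if not acc:
            return False
        return (
            max(p.fold_induction for p in acc) > config.min_max_response
            and is_concentration_dependent(points, config)
        )

    va = _endpoint_verdict(activity_points, config)
    vm = _endpoint_verdict(mrna_points, config)
    if va is Verdict.POSITIVE and vm is Verdict.POSITIVE:
        combined = Verdict.POSITIVE
    elif va is Verdict.POSITIVE or vm is Verdict.POSITIVE:
        combined = Verdict.INDETERMINATE
    else:
        combined = Verdict.NEGATIVE
    return InductionCall(
        activity=va,
        mrna=vm,
        combined=combined,
        fit_eligible={"activity": eligible(activity_points), "mrna": eligible(mrna_points)},
    )


def series_from_frame(df: pd.DataFrame) -> list[ConcentrationSeries]:
    """Group a tidy panel table into ConcentrationSeries.

    Expects columns: compound, lot, endpoint, concentration_um, replicate,
    value, is_vehicle (as written by the synthetic panel generator or any
    equivalent assay export).
    """
    required = {"compound", "lot", "endpoint", "concentration_um", "replicate", "value", "is_vehicle"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"panel table missing columns: {sorted(missing)}")
    if df.empty:
        raise DataError("panel table is empty")
    out = []
    for (compound, lot, endpoint), grp in df.groupby(["compound", "lot", "endpoint"], sort=True):
        vehicle = tuple(grp.loc[grp["is_vehicle"].astype(bool), "value"].astype(float))
        treated = grp.loc[~grp["is_vehicle"].astype(bool)]
        points = tuple(
            (float(conc), tuple(sub["value"].astype(float)))
            for conc, sub in treated.groupby("concentration_um", sort=True)
        )
        out.append(
            ConcentrationSeries(
                compound=str(compound), lot=str(lot), endpoint=str(endpoint),  # type: ignore[arg-type]
                points=points, vehicle=vehicle,
            )
        )
    return out
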