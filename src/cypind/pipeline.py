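"""End-to-end pipeline: wells → QC → fits → RIS → calibration → accuracy.

Composes the analysis stages over a tidy well table and a compound
metadata table, and emits every intermediate product plus a provenance
manifest (config digest, input hashes, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DataError, FitError
from .fitting import CompoundLotResult, collect_fit_table, fit_hill4
from .induction import (
    ExclusionReason,
    FoldIncreasePoint,
    fold_increase_points,
    is_concentration_dependent,
    series_from_frame,
)
from .metrics import AccuracyReport, stratified_report
from .ris import (
    CalibrationModel,
    CompoundRecord,
    RISValue,
    compute_ris,
    fit_calibration,
    predict_auc_change,
    summarize_cutoffs,
    summarize_ris,
)


@dataclass
class PipelineResult:
    points: dict[tuple[str, str, str], list[FoldIncreasePoint]]
    fit_results: dict[tuple[str, str, str], CompoundLotResult]
    fit_tables: dict[str, pd.DataFrame]
    ris_values: list[RISValue]
    ris_summary: pd.DataFrame | None
    ris_grand_cv: dict[str, float]
    calibrations: list[CalibrationModel]
    predictions: pd.DataFrame
    cutoffs: pd.DataFrame | None
    accuracy: list[AccuracyReport]
    manifest: dict = field(default_factory=dict)


def _exclusion_map(panel: pd.DataFrame, exclusions: pd.DataFrame | None):
    """Per-series concentration → reason, from truth flags and user input."""
    excl: dict[tuple[str, str, str], dict[float, str]] = {}
    if "is_toxic_truth" in panel.columns:
        toxic = panel[panel["is_toxic_truth"].astype(bool)]
        for row in toxic.itertuples(index=False):
            key = (row.compound, row.lot, row.endpoint)
            excl.setdefault(key, {})[float(row.concentration_um)] = "toxicity"
    if exclusions is not None:
        for row in exclusions.itertuples(index=False):
            key = (row.compound, row.lot, row.endpoint)
            excl.setdefault(key, {})[float(row.concentration)] = str(row.reason)
    return excl


def run_pipeline(
    panel: pd.DataFrame,
    compounds: list[CompoundRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    exclusions: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every stage over a tidy well table.

    Curve fitting is attempted per compound × lot × endpoint when the QC'd
    series is concentration dependent with maximum fold induction above
    the configured floor; RIS needs an accepted fit plus an unbound C_max;
    calibration uses the flagged calibration-set compounds per lot ×
    endpoint; predictions and stratified accuracy close the loop.
    """
    records = {c.name: c for c in compounds}
    series = series_from_frame(panel)
    excl = _exclusion_map(panel, exclusions)

    points: dict[tuple[str, str, str], list[FoldIncreasePoint]] = {}
    fit_results: dict[tuple[str, str, str], CompoundLotResult] = {}
    for s in series:
        key = (s.compound, s.lot, s.endpoint)
        pts = fold_increase_points(s, config, excl.get(key))
        points[key] = pts
        acc = [p for p in pts if p.accepted]
        max_fi = max((p.fold_induction for p in acc), default=0.0)
        if max_fi <= config.min_max_response:
            fit_results[key] = CompoundLotResult(status="ni", max_fold_induction=max_fi)
        elif not is_concentration_dependent(pts, config):
            fit_results[key] = CompoundLotResult(status="na", max_fold_induction=max_fi)
        else:
            try:
                fit_results[key] = CompoundLotResult(status="fit", fit=fit_hill4(pts, config), max_fold_induction=max_fi)
            except FitError:
                fit_results[key] = CompoundLotResult(status="na", max_fold_induction=max_fi)

    endpoints = sorted({k[2] for k in fit_results})
    fit_tables = {
        ep: collect_fit_table({(c, l): r for (c, l, e), r in fit_results.items() if e == ep})
        for ep in endpoints
    }

    ris_values = []
    for (compound, lot, endpoint), res in fit_results.items():
        rec = records.get(compound)
        if res.status != "fit" or res.fit is None or not res.fit.accepted:
            continue
        if rec is None or rec.cmax_ub is None:
            continue
        ris_values.append(compute_ris(res.fit, rec.cmax_ub, compound, lot, endpoint))

    ris_summary, grand = (None, {})
    lots = sorted({k[1] for k in fit_results})
    if ris_values and len(lots) > 1:
        try:
            ris_summary, grand = summarize_ris(ris_values)
        except DataError:
            pass  # some compounds measured in a single lot only

    ris_by = {(v.compound, v.lot, v.endpoint): v.ris for v in ris_values}
    calibrations = []
    for endpoint in endpoints:
        for lot in lots:
            cal_pairs = [
                (ris_by[(c.name, lot, endpoint)], c.observed_auc_change)
                for c in compounds
                if c.in_calibration_set
                and c.observed_auc_change is not None
                and (c.name, lot, endpoint) in ris_by
            ]
            if len(cal_pairs) >= 4:
                x, y = zip(*cal_pairs)
                calibrations.append(fit_calibration(x, y, lot=lot, endpoint=endpoint))

    pred_rows = []
    for model in calibrations:
        for c in compounds:
            ris = ris_by.get((c.name, model.lot, model.endpoint))
            pred_rows.append({
                "compound": c.name, "lot": model.lot, "endpoint": model.endpoint,
                "ris": ris,
                "predicted_auc_change_pct": predict_auc_change(model, ris),
                "observed_auc_change_pct": c.observed_auc_change,
            })
    predictions = pd.DataFrame(pred_rows)

    cutoffs = summarize_cutoffs(calibrations, config.auc_cutoff_pct) if calibrations else None

    accuracy: list[AccuracyReport] = []
    evaluable = [c for c in compounds if c.observed_auc_change is not None]
    for model in calibrations:
        sub = predictions[(predictions["lot"] == model.lot) & (predictions["endpoint"] == model.endpoint)]
        preds = dict(zip(sub["compound"], sub["predicted_auc_change_pct"]))
        accuracy.extend(stratified_report(preds, evaluable, model.lot, model.endpoint, config))

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "panel_sha256": hashlib.sha256(
            pd.util.hash_pandas_object(panel, index=False).values.tobytes()
        ).hexdigest()[:16],
        "n_series": len(series),
        "n_fits": sum(1 for r in fit_results.values() if r.status == "fit"),
        "n_calibrations": len(calibrations),
    }
    return PipelineResult(
        points=points, fit_results=fit_results, fit_tables=fit_tables,
        ris_values=ris_values, ris_summary=ris_summary, ris_grand_cv=grand,
        calibrations=calibrations, predictions=predictions, cutoffs=cutoffs,
        accuracy=accuracy, manifest=manifest,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write stage outputs and the provenance manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ep, table in result.fit_tables.items():
        table.to_csv(outdir / f"fit_table_{ep}.csv", index=False)
    if result.ris_summary is not None:
        result.ris_summary.to_csv(outdir / "ris_summary.csv", index=False)
    if not result.predictions.empty:
        result.predictions.to_csv(outdir / "predictions.csv", index=False)
    if result.cutoffs is not None:
        result.cutoffs.to_csv(outdir / "ris_cutoffs.csv", index=False)
    if result.calibrations:
        (outdir / "calibrations.json").write_text(json.dumps(
            [m.__dict__ for m in result.calibrations], indent=2))
    if result.accuracy:
        pd.DataFrame([
            {"lot": a.lot, "endpoint": a.endpoint, "subset": a.subset,
             "rmse": a.rmse, "gmfe": a.gmfe, "n_compounds": a.n_compounds}
            for a in result.accuracy
        ]).to_csv(outdir / "accuracy.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
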