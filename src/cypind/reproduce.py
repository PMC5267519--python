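"""Desk-scale reproduction of the published calibration, cutoff and
accuracy results from the packaged per-lot tables.

Everything here recomputes from the printed inputs: Hill-3 calibration
curves are refitted to the published (RIS, observed midazolam AUC change)
pairs for the six calibration compounds; cutoffs come from closed-form
inversion of those fits; accuracy metrics are recomputed from the
published predicted/observed AUC changes.
"""

from __future__ import annotations

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .fixtures import calibration_points, load_compound_records, load_fixtures
from .metrics import stratified_report
from .ris import (
    CalibrationModel,
    RISValue,
    fit_calibration,
    predict_auc_change,
    summarize_cutoffs,
    summarize_ris,
)

LOTS = ("2B", "3A", "3B")


def fit_reference_calibrations(endpoint: str = "mrna", lots: tuple[str, ...] = LOTS) -> list[CalibrationModel]:
    """Refit the per-lot Hill-3 calibration from the published tables."""
    models = []
    for lot in lots:
        _, ris, obs = calibration_points(endpoint=endpoint, lot=lot)
        models.append(fit_calibration(ris, obs, lot=lot, endpoint=endpoint))
    return models


def ris_summary_tables() -> tuple[pd.DataFrame, dict[str, float]]:
    """Cross-lot RIS mean/%CV per compound and grand mean %CV per endpoint."""
    df = load_fixtures("table3_ris")
    values = [
        RISValue(compound=r.compound, lot=r.lot, endpoint=r.endpoint, ris=float(r.ris))
        for r in df.itertuples(index=False)
    ]
    return summarize_ris(values)


def predicted_auc_table(models: list[CalibrationModel]) -> pd.DataFrame:
    """Predicted % AUC change for every compound with a published RIS."""
    ris = load_fixtures("table3_ris")
    rows = []
    for m in models:
        sub = ris[(ris["endpoint"] == m.endpoint) & (ris["lot"] == m.lot)]
        for r in sub.itertuples(index=False):
            rows.append({
                "compound": r.compound, "lot": m.lot, "endpoint": m.endpoint,
                "ris": float(r.ris),
                "predicted_auc_change_pct": predict_auc_change(m, float(r.ris)),
            })
    return pd.DataFrame(rows)


def accuracy_from_published(config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Recompute the accuracy/bias table from published predictions.

    Uses the published predicted AUC changes per lot × endpoint against the
    observed clinical values, stratified by victim-substrate class.
    """
    preds = load_fixtures("table5_auc")
    compounds = [c for c in load_compound_records() if c.observed_auc_change is not None]
    rows = []
    for (endpoint, lot), sub in preds.groupby(["endpoint", "lot"], sort=True):
        pred_map = dict(zip(sub["compound"], sub["predicted_auc_change_pct"].astype(float)))
        for rep in stratified_report(pred_map, compounds, lot, endpoint, config):
            rows.append({
                "lot": rep.lot, "endpoint": rep.endpoint, "subset": rep.subset,
                "rmse": rep.rmse, "gmfe": rep.gmfe, "n_compounds": rep.n_compounds,
                "n_gmfe_excluded": len(rep.excluded),
            })
    return pd.DataFrame(rows)


def reproduce_all(config: PipelineConfig = DEFAULT_CONFIG) -> dict[str, pd.DataFrame]:
    """Run the full fixture-based reproduction; returns tables keyed by name."""
    models = fit_reference_calibrations("mrna") + fit_reference_calibrations("activity")
    cal_table = pd.DataFrame([
        {"lot": m.lot, "endpoint": m.endpoint, "a": m.a, "b": m.b_slope, "c": m.c,
         "r_squared": m.r_squared}
        for m in models
    ])
    cutoffs = summarize_cutoffs(models, config.auc_cutoff_pct)
    summary, grand = ris_summary_tables()
    grand_df = pd.DataFrame([{"endpoint": k, "grand_mean_cv_pct": v} for k, v in sorted(grand.items())])
    return {
        "calibrations": cal_table,
        "cutoffs": cutoffs,
        "ris_summary": summary,
        "ris_grand_cv": grand_df,
        "predictions": predicted_auc_table(models),
        "accuracy": accuracy_from_published(config),
    }
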