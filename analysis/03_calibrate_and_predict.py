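#!/usr/bin/env python
"""Refit the RIS→AUC calibration curves and derive cutoffs and predictions.

Works entirely from the packaged per-lot tables: fits the Hill-3
calibration per lot × endpoint to the six calibration compounds, inverts
each curve at a 20% AUC change for the RIS cutoff, predicts the AUC change
of every compound with a RIS, and summarizes cross-lot RIS reproducibility.
"""

from pathlib import Path

from cypind.reproduce import reproduce_all

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tables = reproduce_all()
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    for name in ("calibrations", "cutoffs", "ris_summary", "ris_grand_cv", "predictions"):
        tables[name].to_csv(outdir / f"{name}.csv", index=False)

    for r in tables["calibrations"].itertuples(index=False):
        print(f"lot {r.lot} ({r.endpoint}): a={r.a:.1f} b={r.b:.2f} c={r.c:.3f} R²={r.r_squared:.3f}")
    cuts = tables["cutoffs"]
    for ep in ("mrna", "activity"):
        mean = cuts.query("endpoint == @ep and lot == 'mean'")["cutoff"].iloc[0]
        print(f"mean RIS cutoff at 20% AUC change ({ep}): {mean:.2f}")
    rif = tables["predictions"].query("compound == 'rifampicin' and endpoint == 'mrna' and lot == '3B'")
    print(f"rifampicin, lot 3B mRNA: predicted AUC change {rif['predicted_auc_change_pct'].iloc[0]:.0f}%")


if __name__ == "__main__":
    main()
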