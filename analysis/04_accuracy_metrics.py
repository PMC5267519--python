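#!/usr/bin/env python
"""Stratified prediction-accuracy metrics from the published AUC tables.

Recomputes RMSE (fractional scale) and GMFE per lot × endpoint for the
full compound set and for the midazolam / non-midazolam victim-substrate
subsets. The headline finding is the substrate effect: a calibration built
on midazolam DDI studies predicts midazolam studies an order of magnitude
more accurately than non-midazolam ones.
"""

from pathlib import Path

from cypind.metrics import round_sig
from cypind.reproduce import accuracy_from_published

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    acc = accuracy_from_published()
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    acc.to_csv(outdir / "accuracy.csv", index=False)

    for subset in ("midazolam", "nonmidazolam"):
        sub = acc[acc["subset"] == subset]
        rmse_range = (sub["rmse"].min(), sub["rmse"].max())
        print(f"{subset}: RMSE {round_sig(rmse_range[0])}–{round_sig(rmse_range[1])}, "
              f"GMFE {round_sig(sub['gmfe'].min())}–{round_sig(sub['gmfe'].max())}")
    mdz = acc.query("subset == 'midazolam'")["rmse"].mean()
    non = acc.query("subset == 'nonmidazolam'")["rmse"].mean()
    print(f"non-midazolam RMSE is {non / mdz:.0f}× the midazolam RMSE on average")


if __name__ == "__main__":
    main()
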