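"""Synthetic induction-panel generator.

Emulates the study design the downstream analysis assumes: a panel of
compounds, each tested at eight log-spaced concentrations in triplicate
across multiple cell lots, with Hill-shaped true concentration-response
on the fold-increase scale, multiplicative log-normal replicate noise,
vehicle-control wells sharing the noise model, and an optional toxicity
regime in which the response collapses above a threshold concentration.

The generator closes the loop for end-to-end testing: given a reference
calibration model it also produces per-compound "observed" clinical AUC
changes from the true parameters, so parameter recovery of every stage —
QC, Hill-4 fitting, RIS, calibration — can be checked against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .fitting import hill4
from .ris import CalibrationModel


class CompoundTruth(BaseModel):
    """True dose-response parameters for one synthetic compound."""

    name: str
    e_max: float = Field(ge=0, description="true maximum fold increase")
    ec50: float = Field(gt=0, description="µM")
    slope: float = Field(1.0, gt=0)
    e_min: float = Field(0.0, ge=0)
    conc_low: float = Field(gt=0, description="lowest tested concentration, µM")
    conc_high: float = Field(gt=0, description="highest tested concentration, µM")
    cmax_ub: float = Field(1.0, gt=0, description="unbound clinical C_max, µM")

    @model_validator(mode="after")
    def _range_ok(self):
        if self.conc_high <= self.conc_low:
            raise ValueError(f"{self.name}: conc_high must exceed conc_low")
        return self


class PanelSpec(BaseModel):
    """Design of a synthetic induction panel."""

    compounds: list[CompoundTruth]
    n_lots: int = Field(3, ge=1)
    n_concentrations: int = Field(8, ge=2)
    n_replicates: int = Field(3, ge=2)
    noise_cv: float = Field(0.10, ge=0, description="fractional replicate CV")
    vehicle_mean: float = Field(100.0, gt=0, description="vehicle-control signal level (activity endpoint)")
    toxicity_threshold: Optional[float] = Field(None, gt=0, description="µM; wells above collapse")
    endpoints: tuple[str, ...] = ("activity", "mrna")
    seed: int = 0

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.compounds:
            raise ValueError("compounds must be non-empty")
        return self

    def concentrations(self, compound: CompoundTruth) -> np.ndarray:
        return np.geomspace(compound.conc_low, compound.conc_high, self.n_concentrations)


@dataclass(frozen=True)
class SyntheticPanel:
    wells: pd.DataFrame  # tidy: compound, lot, endpoint, concentration_um, replicate, value, is_vehicle, is_toxic_truth
    truth: PanelSpec
    observed_auc_change: dict[str, float] | None = None


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


# Fraction of the vehicle signal remaining in the collapsed (toxic) regime.
TOXIC_RESPONSE_FRACTION = 0.1


def generate_panel(spec: PanelSpec) -> SyntheticPanel:
    """Generate a tidy well table from a panel design.

    Each treated well carries vehicle_mean × (1 + Hill4(conc; truth)) ×
    noise for the activity endpoint; mRNA wells carry the equivalent
    per-replicate ΔΔCT, i.e. −log2(fold_induction × noise). Wells above
    the toxicity threshold are drawn from a collapsed-response regime and
    flagged in ``is_toxic_truth``.
    """
    try:
        PanelSpec.model_validate(spec.model_dump())
    except Exception as exc:  # surface the offending field
        raise ConfigurationError(f"invalid panel spec: {exc}") from exc

    rng = np.random.default_rng(spec.seed)
    rows = []
    for lot_i in range(spec.n_lots):
        lot = f"L{lot_i + 1}"
        for comp in spec.compounds:
            concs = spec.concentrations(comp)
            for endpoint in spec.endpoints:
                # vehicle-control wells share the noise model
                veh = spec.vehicle_mean * _noise_factors(rng, spec.noise_cv, spec.n_replicates)
                for r, v in enumerate(veh):
                    value = v if endpoint == "activity" else -math.log2(v / spec.vehicle_mean)
                    rows.append((comp.name, lot, endpoint, 0.0, r, value, True, False))
                for conc in concs:
                    toxic = spec.toxicity_threshold is not None and conc > spec.toxicity_threshold
                    if toxic:
                        mean_signal = spec.vehicle_mean * TOXIC_RESPONSE_FRACTION
                    else:
                        fold = 1.0 + hill4(conc, comp.e_min, comp.e_max, comp.ec50, comp.slope)
                        mean_signal = spec.vehicle_mean * fold
                    vals = mean_signal * _noise_factors(rng, spec.noise_cv, spec.n_replicates)
                    for r, v in enumerate(vals):
                        value = v if endpoint == "activity" else -math.log2(v / spec.vehicle_mean)
                        rows.append((comp.name, lot, endpoint, float(conc), r, float(value), False, toxic))
    wells = pd.DataFrame(
        rows,
        columns=["compound", "lot", "endpoint", "concentration_um", "replicate",
                 "value", "is_vehicle", "is_toxic_truth"],
    )
    return SyntheticPanel(wells=wells, truth=spec)


def generate_calibration_truth(
    spec: PanelSpec,
    cal: CalibrationModel,
    noise_sd_pct: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Per-compound "observed" % AUC change implied by the truth.

    observed = cal.predict(RIS(true E_max, true EC50, C_max,ub)), with
    optional additive Gaussian noise (percentage points).
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    out = {}
    for comp in spec.compounds:
        ris = comp.e_max * comp.cmax_ub / (comp.ec50 + comp.cmax_ub)
        val = float(cal.predict(ris))
        if noise_sd_pct > 0:
            val += float(rng.normal(0.0, noise_sd_pct))
        out[comp.name] = val
    return out


def write_panel(panel: SyntheticPanel, csv_path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write the tidy well CSV and an optional YAML truth sidecar."""
    csv_path = Path(csv_path)
    panel.wells.to_csv(csv_path, index=False)
    if truth_path is not None:
        sidecar = panel.truth.model_dump()
        if panel.observed_auc_change is not None:
            sidecar["observed_auc_change"] = panel.observed_auc_change
        Path(truth_path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


# Reference calibration used by the default panel: a Hill-3 curve in the
# range the calibrated lots exhibit (near-complete AUC loss at high RIS,
# half-maximal effect near RIS 0.35).
DEFAULT_CALIBRATION = CalibrationModel(a=98.0, b_slope=2.5, c=0.35, lot="reference", endpoint="mrna")


def default_panel_spec(seed: int = 0, noise_cv: float = 0.10) -> PanelSpec:
    """The 18-compound, 3-lot, 8-concentration, triplicate design.

    True (E_max, EC50) per compound and tested concentration ranges follow
    the published lot-2B mRNA fits; in vitro non-responders have E_max 0.
    Unbound C_max defaults are back-solved from the published lot-2B RIS
    where one exists, so the true RIS of the default panel matches it.
    """
    from .fixtures import load_fixtures

    fits = load_fixtures("table2_fits")
    ris = load_fixtures("table3_ris")
    ris_2b = ris[(ris["endpoint"] == "mrna") & (ris["lot"] == "2B")].set_index("compound")["ris"]
    compounds = []
    for row in fits[fits["lot"] == "2B"].itertuples(index=False):
        if row.status == "fit":
            e_max, ec50 = float(row.emax), float(row.ec50)
        else:
            e_max, ec50 = 0.0, 1.0
        if e_max > 0 and row.compound in ris_2b.index:
            r = float(ris_2b.loc[row.compound])
            cmax = ec50 * r / (e_max - r)  # invert RIS for the default exposure
        else:
            cmax = 1.0
        compounds.append(
            CompoundTruth(
                name=row.compound, e_max=e_max, ec50=ec50, slope=1.0, e_min=0.0,
                conc_low=float(row.conc_low_um), conc_high=float(row.conc_high_um),
                cmax_ub=cmax,
            )
        )
    return PanelSpec(compounds=compounds, seed=seed, noise_cv=noise_cv)
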