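"""Pipeline configuration.

All decision thresholds used by the analysis stages live here so that no
stage hard-codes them. The defaults are the standard regulatory-science
values for in vitro CYP induction assessment: a 40% replicate CV filter,
an R-squared floor of 0.85 for accepted curve fits, a 1.4-fold maximum
response floor for fit eligibility, a 2-fold positivity threshold, and a
20% victim-drug AUC change defining the RIS cutoff.
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    """Thresholds and numerical settings shared across pipeline stages."""

    cv_threshold: float = Field(0.40, gt=0, lt=1, description="Replicate CV above which a point is rejected")
    r2_min: float = Field(0.85, gt=0, le=1, description="Minimum R² for an accepted curve fit")
    min_max_response: float = Field(1.4, gt=0, description="Fold-induction floor for fit eligibility")
    positive_threshold: float = Field(2.0, gt=0, description="Fold-induction threshold for a positive induction call")
    auc_cutoff_pct: float = Field(20.0, gt=0, description="Predicted %AUC change defining the RIS cutoff")

    # Plateau detection for the observed-max E_max fallback.
    plateau_emax_ratio: float = Field(1.2, gt=1, description="Fitted E_max may exceed the observed max by at most this factor")
    plateau_top_fraction: float = Field(0.9, gt=0, le=1, description="Fitted response at the top concentration must reach this fraction of fitted E_max")

    # Concentration-dependence call.
    min_accepted_points: int = Field(3, ge=2, description="Minimum accepted points for a concentration-dependence call")

    # Stratified accuracy reporting.
    nonmidazolam_exclude: tuple[str, ...] = Field(
        ("clotrimazole",),
        description="Compounds dropped from non-midazolam accuracy metrics (no activity-based RIS)",
    )

    # Report rounding (significant figures), mirroring standard table display.
    report_sigfigs: int = Field(2, ge=1)

    seed: int = Field(0, ge=0)

    model_config = {"frozen": True}

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance manifests."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_CONFIG = PipelineConfig()
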