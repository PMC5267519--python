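"""Packaged reference tables.

Small CSVs transcribing the published per-lot curve-fit parameters, RIS
values and observed/predicted clinical AUC changes for the 18-compound
HepatoCells panel, used for desk-scale reproduction of the calibration,
cutoff and accuracy results. Each table is integrity-checked against a
recorded SHA-256 on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import ConfigurationError, DataError
from .ris import CompoundRecord

_CHECKSUMS = {
    "compounds": "650269900ed0b2fe7ed55dc247e0eac7fb66fede09cb95bd5c9cddd0c2f204ac",
    "table2_fits": "819fbbd0db9f996354244587c12756ea10d46d7efeaa1af558c3588ebad52764",
    "table3_ris": "af2cc156186d6de2ea9a4fb91042cac72d863bb851962e4f6607bca56fb12231",
    "table5_auc": "a468536f85e65eb2abeb1909edd4de8d191e1775bde569ea7a2f611d5db8cdee",
}

FIXTURE_NAMES = tuple(sorted(_CHECKSUMS))


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("cypind.data").joinpath(f"{name}.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _CHECKSUMS[name]
    if digest != expected:
        raise DataError(f"fixture {name} checksum mismatch: {digest} != {expected}")
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_fixtures(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name.

    Available names: compounds, table2_fits, table3_ris, table5_auc.
    """
    if name not in _CHECKSUMS:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return _read(name)


def load_compound_records() -> list[CompoundRecord]:
    """Compound metadata as typed records (clinical panel compounds only)."""
    df = load_fixtures("compounds")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                name=row.name,
                cmax_ub=None if pd.isna(row.cmax_ub_um) else float(row.cmax_ub_um),
                observed_auc_change=None if pd.isna(row.observed_auc_change_pct) else float(row.observed_auc_change_pct),
                substrate_class=None if pd.isna(row.substrate_class) else row.substrate_class,
                in_calibration_set=bool(row.in_calibration_set),
                category=None if pd.isna(row.category) else row.category,
            )
        )
    return records


def calibration_points(endpoint: str = "mrna", lot: str = "3B") -> tuple[list[str], list[float], list[float]]:
    """(compounds, RIS, observed %AUC change) for the calibration set.

    RIS comes from the published per-lot table; observed midazolam AUC
    changes from the compound metadata.
    """
    ris = load_fixtures("table3_ris")
    records = {c.name: c for c in load_compound_records()}
    cal = [name for name, rec in records.items() if rec.in_calibration_set]
    sub = ris[(ris["endpoint"] == endpoint) & (ris["lot"] == lot) & ris["compound"].isin(cal)]
    names = list(sub["compound"])
    x = [float(v) for v in sub["ris"]]
    y = [float(records[n].observed_auc_change) for n in names]
    if len(names) < 4:
        raise ConfigurationError(f"calibration set too small for {endpoint}/{lot}")
    return names, x, y
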