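"""Tables, configuration and unit utilities.

All tables are plain CSV (comma-separated, UTF-8, header row mandatory,
"." decimal separator).  The count-table schema is::

    host, inoculum, vitamin, replicate, time_h, count_per_uL

with time_h >= 0 in hours since inoculation, strictly positive counts in
cells/µL, and a unique (host, inoculum, vitamin, replicate, time_h) key.
Parameter tables carry one row per replicate (growth, decline,
max_abundance, fit_converged) and report tables carry one contrast per
row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidCountError, SchemaError
from .model import FitOptions, TimeSeries

__all__ = ["COUNT_COLUMNS", "read_count_table", "write_count_table",
           "read_parameter_table", "write_parameter_table",
           "write_report_tables", "mass_to_molar", "F2_VITAMIN_DOSES",
           "RunConfig"]

COUNT_COLUMNS = ("host", "inoculum", "vitamin", "replicate",
                 "time_h", "count_per_uL")
PARAMETER_COLUMNS = ("host", "inoculum", "vitamin", "replicate",
                     "growth", "decline", "max_abundance", "fit_converged")
_KEY = ["host", "inoculum", "vitamin", "replicate", "time_h"]


def read_count_table(path) -> list[TimeSeries]:
    """Read a tidy count CSV into per-replicate :class:`TimeSeries`.

    Validates the schema and reports offending rows by their 1-based data
    row number (header excluded).
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    for col in ("time_h", "count_per_uL"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() | ~np.isfinite(vals))
        if len(bad):
            raise SchemaError(f"non-numeric {col} at row {bad[0] + 1}")
        df[col] = vals
    bad = np.flatnonzero((df["count_per_uL"] <= 0).to_numpy())
    if len(bad):
        raise InvalidCountError(
            f"non-positive count_per_uL at row {bad[0] + 1}")
    bad = np.flatnonzero((df["time_h"] < 0).to_numpy())
    if len(bad):
        raise SchemaError(f"negative time_h at row {bad[0] + 1}")
    dup = np.flatnonzero(df.duplicated(subset=_KEY).to_numpy())
    if len(dup):
        raise SchemaError(f"duplicate (replicate, time) key at row {dup[0] + 1}")
    from .simulate import series_from_table
    return series_from_table(df)


def write_count_table(df: pd.DataFrame, path) -> None:
    if len(df) == 0:
        raise EmptyInputError("refusing to write an empty count table")
    df.to_csv(path, index=False)


def write_parameter_table(records, path) -> None:
    """Write per-replicate parameters (ReplicateParameters or a frame)."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.as_dict() for r in records])
    if len(records) == 0:
        raise EmptyInputError("refusing to write an empty parameter table")
    missing = [c for c in PARAMETER_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records[list(PARAMETER_COLUMNS)].to_csv(
        path, index=False)


def read_parameter_table(path) -> pd.DataFrame:
    """Read a per-replicate parameter CSV (the inference input).

    A missing ``fit_converged`` column (e.g. an externally supplied table
    of already-vetted fits) is filled with True.
    """
    df = pd.read_csv(path)
    missing = [c for c in PARAMETER_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    present = [c for c in ("growth", "decline", "max_abundance")
               if c in df.columns]
    if not present:
        raise SchemaError("no response column present")
    if "fit_converged" not in df.columns:
        df["fit_converged"] = True
    return df


def write_report_tables(tables, out_dir) -> dict[str, str]:
    """Write the three impact tables as CSVs under ``out_dir``.

    ``tables`` is an :class:`~bloomfit.inference.ImpactTables`; rows are
    already ordered by host, response, comparison.  Returns the mapping of
    table name to written path.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.as_dict().items():
        p = out / f"impacts_{name}.csv"
        df.to_csv(p, index=False)
        written[name] = str(p)
    return written


# ---------------------------------------------------------------------
# units

#: f/2 medium vitamin doses: (mass concentration µg/L, molar mass g/mol)
#: for thiamine·HCl (B1), biotin (B7) and cyanocobalamin (B12).
F2_VITAMIN_DOSES = {
    "B1": (100.0, 337.27),
    "B7": (0.5, 244.31),
    "B12": (0.5, 1355.37),
}


def mass_to_molar(mass_concentration_ug_per_L: float,
                  molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration (µg/L) to picomolar.

    (mass * 1e-6 g / molar mass) mol/L * 1e12 pM/M.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    if mass_concentration_ug_per_L < 0:
        raise ValueError("mass concentration must be >= 0")
    return mass_concentration_ug_per_L * 1e-6 / molar_mass_g_per_mol * 1e12


# ---------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Flat key-value run configuration (YAML on disk).

    Every key has a default except the seed, which is mandatory for any
    stochastic step.
    """

    seed: int | None = None
    alpha: float = 0.05
    adjust: str = "tukey"
    peak_method: str = "mean_of_ln"
    control_label: str = "control"
    replicates: int = 3
    count_cv: float = 0.05
    param_jitter_cv: float = 0.05
    fit: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fit_keys = {f: raw.pop(f) for f in list(raw)
                    if f in FitOptions.__dataclass_fields__}
        known = set(cls.__dataclass_fields__) - {"fit"}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(fit=FitOptions(**fit_keys), **raw)
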