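"""End-to-end orchestration: speciation -> aggregation -> fitting -> reports.

Takes a replicate assay-record table (delimited text), computes the fitting
abscissa for each condition (speciated Mg2PPi or total PPi), aggregates
replicates into weighted mean points, applies the substrate-inhibition
truncation, fits the requested rate laws, and emits a parameter table plus a
salt-sensitivity summary (percent decrease of Vm versus the no-added-NaCl
reference, and fold changes).

All tables are plain tab-separated text; full numeric precision is kept in
the machine-readable outputs, with a human-readable "estimate +/- SE" mirror
formatted to two significant figures of the SE.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import (
    FitError,
    FitResult,
    MODEL_PARAM_NAMES,
    UnderdeterminedError,
    aggregate_replicates,
    fit_model,
)
from .speciation import ComplexationConstants, IonicConditions, SpeciationError, speciate

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "AnalysisConfig",
    "AnalysisResult",
    "read_assay_table",
    "write_table",
    "conditions_for_row",
    "run_analysis",
    "relative_change",
    "salt_sensitivity_summary",
    "format_estimate",
]

REQUIRED_COLUMNS = (
    "enzyme",
    "mode",
    "nacl_mM",
    "kcl_mM",
    "ppi_total_mM",
    "ph",
    "replicate_id",
    "rate_U_per_mg",
)
OPTIONAL_COLUMNS = ("mgcl2_mM",)

_NUMERIC = ("nacl_mM", "kcl_mM", "mgcl2_mM", "ppi_total_mM", "ph", "rate_U_per_mg")
_NONNEGATIVE = ("nacl_mM", "kcl_mM", "mgcl2_mM", "ppi_total_mM")


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a replicate assay-record table (TSV).

    Column order is irrelevant; unknown columns are rejected so silent schema
    drift cannot pass unnoticed.  Errors name the offending 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory record table against the input schema."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay table missing required column(s): {missing}")
    unknown = [
        c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    ]
    if unknown:
        raise ValueError(f"assay table has unknown column(s): {unknown}")
    if len(df) == 0:
        raise ValueError("assay table contains no data rows")
    df = df.copy()
    if "mgcl2_mM" not in df.columns:
        df["mgcl2_mM"] = np.nan

    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        allowed_na = converted.isna() & df[col].isna()
        bad = converted.isna() & ~allowed_na
        if col != "mgcl2_mM" and df[col].isna().any():
            bad |= df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"column {col!r}: non-numeric or missing value at data row {row}")
        df[col] = converted

    for col in _NONNEGATIVE:
        neg = df[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0]) + 1
            raise ValueError(f"column {col!r}: negative concentration at data row {row}")
    bad_rate = ~np.isfinite(df["rate_U_per_mg"].to_numpy())
    if bad_rate.any():
        row = int(np.flatnonzero(bad_rate)[0]) + 1
        raise ValueError(f"non-finite rate at data row {row}")

    bad_mode = ~df["mode"].isin(["matched_mg", "fixed_mg"])
    if bad_mode.any():
        row = int(np.flatnonzero(bad_mode.to_numpy())[0]) + 1
        raise ValueError(f"invalid mode at data row {row} (matched_mg|fixed_mg)")
    fixed_missing = (df["mode"] == "fixed_mg") & df["mgcl2_mM"].isna()
    if fixed_missing.any():
        row = int(np.flatnonzero(fixed_missing.to_numpy())[0]) + 1
        raise ValueError(f"fixed_mg row without mgcl2_mM at data row {row}")
    # canonical column order for byte-identical round trips
    return df[list(REQUIRED_COLUMNS[:4]) + ["mgcl2_mM"] + list(REQUIRED_COLUMNS[4:])]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV at full float precision (repr round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def conditions_for_row(row: Mapping) -> IonicConditions:
    """Reconstruct the ionic totals of one record from its metadata columns.

    Applies the design rules: matched mode sets total Mg = 2 x PPi; the
    tetrasodium-salt rule adds basal Na+ = 4 x PPi to the added NaCl.
    """
    ppi = float(row["ppi_total_mM"])
    if row["mode"] == "matched_mg":
        mg = 2.0 * ppi
    else:
        mg = float(row["mgcl2_mM"])
    return IonicConditions(
        total_ppi=ppi,
        total_mg=mg,
        total_k=float(row["kcl_mM"]),
        total_na=float(row["nacl_mM"]) + 4.0 * ppi,
        ph=float(row["ph"]),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Options for :func:`run_analysis`.

    ``abscissa``: ``"speciated"`` fits against S = [Mg2PPi]; ``"total_ppi"``
    against total PPi; ``"auto"`` (default) uses speciated substrate for
    matched-Mg conditions and total PPi for fixed-Mg titrations, matching how
    the two designs are conventionally plotted.

    ``truncate_max_s``: substrate-inhibition cutoff (mM, on the fitting
    abscissa); either one value for all enzymes or a mapping per enzyme name.
    """

    models: tuple[str, ...] = ("hill", "mwc")
    abscissa: str = "auto"
    truncate_max_s: float | Mapping[str, float] | None = None
    weights: str = "replicate-variance"
    single_replicate: str = "error"
    constants: ComplexationConstants | None = None

    def __post_init__(self) -> None:
        if self.abscissa not in ("auto", "speciated", "total_ppi"):
            raise ValueError(f"invalid abscissa {self.abscissa!r}")
        for model in self.models:
            if model not in MODEL_PARAM_NAMES:
                raise ValueError(f"unknown model {model!r}")

    def truncation_for(self, enzyme: str) -> float | None:
        if self.truncate_max_s is None:
            return None
        if isinstance(self.truncate_max_s, Mapping):
            return self.truncate_max_s.get(enzyme)
        return float(self.truncate_max_s)


@dataclass(frozen=True)
class AnalysisResult:
    parameter_table: pd.DataFrame
    sensitivity: pd.DataFrame
    log: tuple[str, ...]
    manifest: dict


_PARAM_COLUMNS = ("vm", "k_half", "n_h", "l", "k_r", "km")


def _result_row(
    key: dict, model: str, abscissa: str, fit: FitResult | None, note: str
) -> dict:
    row = dict(key)
    row["model"] = model
    row["abscissa"] = abscissa
    for name in _PARAM_COLUMNS:
        row[name] = np.nan
        row[f"{name}_se"] = np.nan
        row[f"{name}_display"] = ""
    if fit is not None:
        for name, est in fit.params.items():
            row[name] = est
            row[f"{name}_se"] = fit.se[name]
            row[f"{name}_display"] = format_estimate(est, fit.se[name])
        row["wrss"] = fit.wrss
        row["points_used"] = fit.points_used
        row["truncation_max_s"] = (
            np.nan if fit.truncation_max_s is None else fit.truncation_max_s
        )
        row["converged"] = fit.converged
        note = "; ".join(filter(None, [note, *fit.warnings]))
    else:
        row["wrss"] = np.nan
        row["points_used"] = 0
        row["truncation_max_s"] = np.nan
        row["converged"] = False
    row["note"] = note
    return row


def run_analysis(records: pd.DataFrame, config: AnalysisConfig | None = None):
    """Run the full pipeline on a validated record table.

    Per (enzyme, design, NaCl level) condition: compute the abscissa
    (speciating each point when requested), aggregate replicates, truncate
    the substrate-inhibited region, and fit every configured model.  A
    condition that fails (underdetermined after truncation, speciation or
    fit failure) is flagged in its row and the run continues.

    Returns an :class:`AnalysisResult` with the parameter table, the
    salt-sensitivity summary, the warning log, and a run manifest recording
    the configuration and constants actually used.
    """
    config = config or AnalysisConfig()
    records = validate_records(records)
    constants = config.constants or ComplexationConstants.default()
    log: list[str] = []
    rows: list[dict] = []

    group_cols = ["enzyme", "mode", "mgcl2_mM", "nacl_mM"]
    for (enzyme, mode, mgcl2, nacl), grp in records.groupby(
        group_cols, dropna=False, sort=True
    ):
        key = {
            "enzyme": enzyme,
            "mode": mode,
            "mgcl2_mM": mgcl2,
            "nacl_mM": nacl,
        }
        label = f"{enzyme}/{mode}/NaCl={nacl}"
        abscissa = config.abscissa
        if abscissa == "auto":
            abscissa = "speciated" if mode == "matched_mg" else "total_ppi"

        try:
            if abscissa == "speciated":
                s_values = np.array(
                    [
                        speciate(conditions_for_row(row), constants).substrate
                        for _, row in grp.iterrows()
                    ]
                )
            else:
                s_values = grp["ppi_total_mM"].to_numpy(dtype=float)
        except SpeciationError as exc:
            log.append(f"{label}: speciation failed ({exc})")
            for model in config.models:
                rows.append(_result_row(key, model, abscissa, None, str(exc)))
            continue

        try:
            dataset = aggregate_replicates(
                s_values,
                grp["rate_U_per_mg"].to_numpy(dtype=float),
                metadata=key,
                single_replicate=config.single_replicate,
            )
        except ValueError as exc:
            log.append(f"{label}: aggregation failed ({exc})")
            for model in config.models:
                rows.append(_result_row(key, model, abscissa, None, str(exc)))
            continue

        max_s = config.truncation_for(str(enzyme))
        for model in config.models:
            try:
                fit = fit_model(
                    dataset,
                    model,
                    weights=config.weights,
                    truncate_max_s=max_s,
                )
            except (UnderdeterminedError, FitError, ValueError) as exc:
                log.append(f"{label}/{model}: fit failed ({exc})")
                rows.append(_result_row(key, model, abscissa, None, str(exc)))
                continue
            for w in fit.warnings:
                log.append(f"{label}/{model}: {w}")
            rows.append(_result_row(key, model, abscissa, fit, ""))

    table = pd.DataFrame(rows)
    sensitivity = salt_sensitivity_summary(table, strict=False)

    config_desc = {
        "models": list(config.models),
        "abscissa": config.abscissa,
        "truncate_max_s": (
            dict(config.truncate_max_s)
            if isinstance(config.truncate_max_s, Mapping)
            else config.truncate_max_s
        ),
        "weights": config.weights,
        "single_replicate": config.single_replicate,
    }
    manifest = {
        "config": config_desc,
        "config_sha256": hashlib.sha256(
            json.dumps(config_desc, sort_keys=True).encode()
        ).hexdigest(),
        "constants_kd_mM": dict(constants.kd),
        "n_records": int(len(records)),
        "n_conditions": int(records.groupby(group_cols, dropna=False).ngroups),
    }
    return AnalysisResult(table, sensitivity, tuple(log), manifest)


def relative_change(reference: float, treated: float) -> dict[str, float]:
    """Percent decrease and fold change of a rate or Vm versus a reference.

    percent_decrease = 100 * (1 - treated/reference); fold_change =
    treated/reference (the convention for "n-fold activation" summaries).
    """
    if not (reference > 0):
        raise ValueError(f"reference must be > 0, got {reference!r}")
    if treated < 0:
        raise ValueError(f"treated must be >= 0, got {treated!r}")
    fold = treated / reference
    return {"percent_decrease": 100.0 * (1.0 - fold), "fold_change": fold}


def salt_sensitivity_summary(
    table: pd.DataFrame, *, strict: bool = True
) -> pd.DataFrame:
    """Per-enzyme Vm sensitivity to added NaCl, versus the 0-mM reference.

    ``table`` must carry columns enzyme, nacl_mM and vm (a parameter table
    from :func:`run_analysis`, or any frame shaped like one); model, mode and
    mgcl2_mM columns, when present, become additional grouping keys.  Percent
    decreases are reported raw and rounded to the nearest ten percentage
    points (the granularity of narrative summaries).

    With ``strict=True`` a group lacking the 0-mM-NaCl reference row raises;
    ``strict=False`` logs it into the output as an empty group (used by
    :func:`run_analysis`, which must not abort a whole run).
    """
    for col in ("enzyme", "nacl_mM", "vm"):
        if col not in table.columns:
            raise ValueError(f"parameter table lacks required column {col!r}")
    group_cols = [
        c for c in ("enzyme", "model", "mode", "mgcl2_mM") if c in table.columns
    ]
    out_rows: list[dict] = []
    for gkey, grp in table.groupby(group_cols, dropna=False, sort=True):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        ref_rows = grp[(grp["nacl_mM"] == 0) & np.isfinite(grp["vm"])]
        if len(ref_rows) == 0:
            if strict:
                label = ", ".join(f"{c}={v}" for c, v in zip(group_cols, gkey))
                raise ValueError(
                    f"no 0-mM-NaCl reference row with a finite Vm for {label}"
                )
            continue
        ref_vm = float(ref_rows["vm"].iloc[0])
        for _, row in grp.sort_values("nacl_mM").iterrows():
            if row["nacl_mM"] == 0 or not np.isfinite(row["vm"]):
                continue
            change = relative_change(ref_vm, float(row["vm"]))
            out = dict(zip(group_cols, gkey))
            out.update(
                {
                    "nacl_mM": row["nacl_mM"],
                    "vm_reference": ref_vm,
                    "vm": float(row["vm"]),
                    "percent_decrease": change["percent_decrease"],
                    "percent_decrease_rounded10": 10.0
                    * round(change["percent_decrease"] / 10.0),
                    "fold_change": change["fold_change"],
                }
            )
            out_rows.append(out)
    columns = group_cols + [
        "nacl_mM",
        "vm_reference",
        "vm",
        "percent_decrease",
        "percent_decrease_rounded10",
        "fold_change",
    ]
    return pd.DataFrame(out_rows, columns=columns)


def format_estimate(estimate: float, se: float) -> str:
    """Format "estimate +/- SE" with the SE at two significant figures.

    The estimate is rounded to the SE's decimal place, the convention of
    kinetic parameter tables; full precision stays in the numeric columns.
    """
    if not np.isfinite(estimate):
        return "nan"
    if not np.isfinite(se) or se <= 0:
        return f"{estimate:g}"
    exponent = math.floor(math.log10(se))
    decimals = max(0, 1 - exponent)
    return f"{round(estimate, decimals):.{decimals}f} ± {round(se, decimals):.{decimals}f}"
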