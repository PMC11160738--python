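"""Reading and writing the package's delimited-text formats.

Formats handled here:

* long-format transition quantification reports (CSV or TSV, auto-detected),
  the export one obtains from chromatogram-extraction software after a
  peptide-centric DIA search;
* retention-time standards tables (one row per standard transition, the
  peptide-level fields repeated);
* assay tables (one row per selected transition);
* instrument-ready transition lists in two dialects, ``"instrument"``
  (Compound / RT / window / m/z / CE) and ``"skyline"`` (protein, modified
  sequence, precursor and product m/z, fragment ion);
* the YAML run configuration mirroring SelectionConfig + ScheduleConfig.

m/z values are written with 4 decimal places, retention times and
collision energies with 2.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    ConfigurationError,
    DataError,
    KEY_COLUMNS,
    REPORT_COLUMNS,
    ScheduleConfig,
    SelectionConfig,
    StandardPeptide,
    StateError,
    _NUMERIC_COLUMNS,
)

logger = logging.getLogger(__name__)

_STRING_COLUMNS = ("protein_id", "peptide_seq", "product_ion", "replicate_id")


@dataclass
class ReportReadResult:
    """Validated records plus the rows rejected during validation.

    ``records`` holds the canonical report columns; ``rejected`` has one
    row per discarded input line with its 1-based file row number and the
    reason.  No row is silently dropped:
    input data rows == len(records) + len(rejected).
    """

    records: pd.DataFrame
    rejected: pd.DataFrame


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", newline="") as handle:
        header = handle.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_transition_report(
    path: str, column_map: Optional[Mapping[str, str]] = None
) -> ReportReadResult:
    """Read and validate a long-format transition report.

    Parameters
    ----------
    path:
        Delimited text file (comma or tab, auto-detected) with a header row.
    column_map:
        Optional mapping from canonical field name to the header actually
        used in the file, e.g. ``{"peptide_seq": "Peptide Modified Sequence"}``.

    Raises
    ------
    ConfigurationError
        If a required column is absent (the message names it).
    DataError
        On unreadable numeric cells (with the file row number) or
        duplicate (protein, peptide, charge, product ion, replicate) keys.
    """
    if not os.path.exists(path):
        raise DataError(f"report file not found: {path}")
    frame = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str, keep_default_na=False)
    if column_map:
        rename = {actual: canonical for canonical, actual in column_map.items()}
        frame = frame.rename(columns=rename)
    for column in REPORT_COLUMNS:
        if column not in frame.columns:
            raise ConfigurationError(f"report is missing required column {column!r}")
    frame = frame.loc[:, list(REPORT_COLUMNS)].copy()
    # header is file row 1; first data row is file row 2
    frame["_row"] = frame.index + 2

    for column in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(frame[column], errors="coerce")
        bad = converted.isna() & (frame[column].str.strip() != "")
        empty = frame[column].str.strip() == ""
        unreadable = bad | empty
        if unreadable.any():
            row = int(frame.loc[unreadable, "_row"].iloc[0])
            raise DataError(f"unreadable numeric value in column {column!r} at file row {row}")
        frame[column] = converted
    charge = pd.to_numeric(frame["precursor_charge"], errors="coerce")
    if charge.isna().any() or (charge != charge.round()).any():
        row = int(frame.loc[charge.isna() | (charge != charge.round()), "_row"].iloc[0])
        raise DataError(f"unreadable integer charge at file row {row}")
    frame["precursor_charge"] = charge.astype(int)

    duplicated = frame.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if duplicated.any():
        first = frame.loc[duplicated, list(KEY_COLUMNS)].iloc[0]
        raise DataError(
            "duplicate transition key: "
            + ", ".join(f"{k}={first[k]!r}" for k in KEY_COLUMNS)
        )

    reasons = pd.Series("", index=frame.index, dtype=str)
    for column in _STRING_COLUMNS:
        reasons[(frame[column].str.strip() == "") & (reasons == "")] = f"empty {column}"
    reasons[(frame["precursor_charge"] < 1) & (reasons == "")] = "precursor_charge < 1"
    reasons[(frame["precursor_mz"] <= 0) & (reasons == "")] = "precursor_mz <= 0"
    reasons[(frame["product_mz"] <= 0) & (reasons == "")] = "product_mz <= 0"
    reasons[(frame["area"] < 0) & (reasons == "")] = "negative area"
    reasons[(frame["apex_rt"] < 0) & (reasons == "")] = "negative apex_rt"

    bad_rows = reasons != ""
    rejected = frame.loc[bad_rows, ["_row"] + list(REPORT_COLUMNS)].copy()
    rejected.insert(1, "reason", reasons[bad_rows])
    rejected = rejected.rename(columns={"_row": "row"}).reset_index(drop=True)
    if len(rejected):
        logger.warning(
            "rejected %d invalid report row(s); first at file row %d (%s)",
            len(rejected),
            int(rejected["row"].iloc[0]),
            rejected["reason"].iloc[0],
        )
    records = frame.loc[~bad_rows, list(REPORT_COLUMNS)].reset_index(drop=True)
    return ReportReadResult(records=records, rejected=rejected)


def write_transition_report(frame: pd.DataFrame, path: str) -> None:
    """Write a canonical report DataFrame as CSV (the synthetic generator's output format)."""
    frame.loc[:, list(REPORT_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Standards
# ---------------------------------------------------------------------------

STANDARDS_COLUMNS = (
    "name",
    "irt",
    "measured_rt",
    "precursor_mz",
    "precursor_charge",
    "product_ion",
    "product_mz",
)


def read_standards(path: str) -> list[StandardPeptide]:
    """Read a standards table (one row per standard transition).

    Required columns: ``name`` and ``irt``.  ``measured_rt``,
    ``precursor_mz``, ``precursor_charge`` and the product-ion columns are
    optional; without product columns a standard carries no transitions
    (usable for calibration but not for method export).
    """
    if not os.path.exists(path):
        raise DataError(f"standards file not found: {path}")
    frame = pd.read_csv(path, sep=_sniff_delimiter(path))
    for column in ("name", "irt"):
        if column not in frame.columns:
            raise ConfigurationError(f"standards file is missing required column {column!r}")
    standards = []
    for name, group in frame.groupby("name", sort=False):
        first = group.iloc[0]

        def _opt(col, cast=float):
            if col not in group.columns or pd.isna(first[col]):
                return None
            return cast(first[col])

        transitions = []
        if "product_mz" in group.columns:
            for row in group.itertuples(index=False):
                if not pd.isna(row.product_mz):
                    label = getattr(row, "product_ion", None)
                    transitions.append(
                        (str(label) if label is not None and not pd.isna(label) else "", float(row.product_mz))
                    )
        std = StandardPeptide(
            name=str(name),
            irt=float(first["irt"]),
            measured_rt=_opt("measured_rt"),
            precursor_mz=_opt("precursor_mz"),
            precursor_charge=_opt("precursor_charge", int),
            transitions=transitions,
        )
        std.validate()
        standards.append(std)
    if len({s.name for s in standards}) != len(standards):
        raise DataError("standard peptide names are not unique")
    return standards


def write_standards(standards: Sequence[StandardPeptide], path: str) -> None:
    rows = []
    for std in standards:
        transitions = std.transitions or [(None, None)]
        for ion, mz in transitions:
            rows.append(
                {
                    "name": std.name,
                    "irt": std.irt,
                    "measured_rt": std.measured_rt,
                    "precursor_mz": std.precursor_mz,
                    "precursor_charge": std.precursor_charge,
                    "product_ion": ion,
                    "product_mz": mz,
                }
            )
    pd.DataFrame(rows, columns=list(STANDARDS_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assay tables (selected targets, one row per transition)
# ---------------------------------------------------------------------------

ASSAY_COLUMNS = (
    "protein_id",
    "peptide_seq",
    "precursor_charge",
    "precursor_mz",
    "product_ion",
    "product_mz",
    "intensity_rank",
    "cv_pct",
    "mean_summed_area",
    "irt",
)


def write_assay(targets, path: str) -> None:
    """Write selected assay targets, one row per transition."""
    rows = []
    for target in targets:
        for transition in target.transitions:
            rows.append(
                {
                    "protein_id": target.protein_id,
                    "peptide_seq": target.peptide_seq,
                    "precursor_charge": target.precursor_charge,
                    "precursor_mz": target.precursor_mz,
                    "product_ion": transition.product_ion,
                    "product_mz": transition.product_mz,
                    "intensity_rank": transition.rank,
                    "cv_pct": target.cv_pct,
                    "mean_summed_area": target.mean_summed_area,
                    "irt": target.irt,
                }
            )
    pd.DataFrame(rows, columns=list(ASSAY_COLUMNS)).to_csv(path, index=False)


def read_assay(path: str):
    """Read an assay table back into AssayTarget objects."""
    from .selection import AssayTarget, AssayTransition

    if not os.path.exists(path):
        raise DataError(f"assay file not found: {path}")
    frame = pd.read_csv(path)
    for column in ASSAY_COLUMNS[:7]:
        if column not in frame.columns:
            raise ConfigurationError(f"assay file is missing required column {column!r}")
    targets = []
    for key, group in frame.groupby(
        ["protein_id", "peptide_seq", "precursor_charge"], sort=False
    ):
        group = group.sort_values("intensity_rank")
        first = group.iloc[0]
        irt = first.get("irt")
        targets.append(
            AssayTarget(
                protein_id=str(key[0]),
                peptide_seq=str(key[1]),
                precursor_charge=int(key[2]),
                precursor_mz=float(first["precursor_mz"]),
                transitions=[
                    AssayTransition(
                        product_ion=str(r.product_ion),
                        product_mz=float(r.product_mz),
                        rank=int(r.intensity_rank),
                    )
                    for r in group.itertuples(index=False)
                ],
                cv_pct=float(first["cv_pct"]) if "cv_pct" in group.columns else float("nan"),
                mean_summed_area=float(first["mean_summed_area"])
                if "mean_summed_area" in group.columns
                else float("nan"),
                irt=None if irt is None or pd.isna(irt) else float(irt),
            )
        )
    return targets


# ---------------------------------------------------------------------------
# Instrument transition lists
# ---------------------------------------------------------------------------

INSTRUMENT_COLUMNS = (
    "Compound",
    "Retention Time (min)",
    "RT Window (min)",
    "Precursor (m/z)",
    "Product (m/z)",
    "Collision Energy (V)",
)

SKYLINE_COLUMNS = (
    "Protein Name",
    "Peptide Modified Sequence",
    "Precursor Mz",
    "Precursor Charge",
    "Product Mz",
    "Fragment Ion",
)


def _mz(x: float) -> str:
    return f"{x:.4f}"


def _rt(x: float) -> str:
    return f"{x:.2f}"


def _method_rows_instrument(method) -> list[dict]:
    rows = []
    for target in method.targets:
        if target.predicted_rt is None or target.window is None:
            raise StateError(
                f"target {target.peptide_seq}/{target.precursor_charge} has no retention-time assignment"
            )
        if target.collision_energy is None:
            raise StateError(
                f"target {target.peptide_seq}/{target.precursor_charge} has no collision energy"
            )
        width = target.window[1] - target.window[0]
        for transition in target.transitions:
            rows.append(
                {
                    "Compound": f"{target.peptide_seq}.{target.precursor_charge}.{transition.product_ion}",
                    "Retention Time (min)": _rt(target.predicted_rt),
                    "RT Window (min)": _rt(width),
                    "Precursor (m/z)": _mz(target.precursor_mz),
                    "Product (m/z)": _mz(transition.product_mz),
                    "Collision Energy (V)": _rt(target.collision_energy),
                }
            )
    mid = method.gradient_length_min / 2.0
    for std in method.standards:
        for ion, product_mz in std.transitions:
            if std.precursor_mz is None or std.collision_energy is None:
                raise StateError(f"standard {std.name} lacks precursor m/z or collision energy")
            rows.append(
                {
                    "Compound": f"{std.name}.{ion}",
                    "Retention Time (min)": _rt(mid),
                    "RT Window (min)": _rt(method.gradient_length_min),
                    "Precursor (m/z)": _mz(std.precursor_mz),
                    "Product (m/z)": _mz(product_mz),
                    "Collision Energy (V)": _rt(std.collision_energy),
                }
            )
    return rows


def _method_rows_skyline(method) -> list[dict]:
    rows = []
    for target in method.targets:
        if target.predicted_rt is None:
            raise StateError(
                f"target {target.peptide_seq}/{target.precursor_charge} has no retention-time assignment"
            )
        for transition in target.transitions:
            rows.append(
                {
                    "Protein Name": target.protein_id,
                    "Peptide Modified Sequence": target.peptide_seq,
                    "Precursor Mz": _mz(target.precursor_mz),
                    "Precursor Charge": target.precursor_charge,
                    "Product Mz": _mz(transition.product_mz),
                    "Fragment Ion": transition.product_ion,
                }
            )
    for std in method.standards:
        for ion, product_mz in std.transitions:
            if std.precursor_mz is None:
                raise StateError(f"standard {std.name} lacks precursor m/z")
            rows.append(
                {
                    "Protein Name": "Standards",
                    "Peptide Modified Sequence": std.name,
                    "Precursor Mz": _mz(std.precursor_mz),
                    "Precursor Charge": std.precursor_charge or "",
                    "Product Mz": _mz(product_mz),
                    "Fragment Ion": ion,
                }
            )
    return rows


def write_transition_list(
    methods: Sequence, dialect: str, out_dir: str, stem: str = "method"
) -> list[str]:
    """Write one transition-list file per scheduled method.

    Returns the list of file paths written (``<out_dir>/<stem>_NN.csv``).
    An empty method collection writes nothing and logs a warning.
    """
    if dialect not in ("instrument", "skyline"):
        raise ConfigurationError(f"unknown transition-list dialect {dialect!r}")
    methods = list(methods)
    if not methods:
        logger.warning("no scheduled methods to write; no transition lists produced")
        return []
    os.makedirs(out_dir, exist_ok=True)
    columns = INSTRUMENT_COLUMNS if dialect == "instrument" else SKYLINE_COLUMNS
    builder = _method_rows_instrument if dialect == "instrument" else _method_rows_skyline
    paths = []
    for method in methods:
        rows = builder(method)
        path = os.path.join(out_dir, f"{stem}_{method.index:02d}.csv")
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        paths.append(path)
    return paths


def read_transition_list(path: str, dialect: str = "skyline") -> pd.DataFrame:
    """Read a transition list back as a DataFrame with canonical-ish columns."""
    if dialect not in ("instrument", "skyline"):
        raise ConfigurationError(f"unknown transition-list dialect {dialect!r}")
    frame = pd.read_csv(path)
    if dialect == "skyline":
        rename = {
            "Protein Name": "protein_id",
            "Peptide Modified Sequence": "peptide_seq",
            "Precursor Mz": "precursor_mz",
            "Precursor Charge": "precursor_charge",
            "Product Mz": "product_mz",
            "Fragment Ion": "product_ion",
        }
    else:
        rename = {
            "Compound": "compound",
            "Retention Time (min)": "retention_time",
            "RT Window (min)": "rt_window",
            "Precursor (m/z)": "precursor_mz",
            "Product (m/z)": "product_mz",
            "Collision Energy (V)": "collision_energy",
        }
    missing = [c for c in rename if c not in frame.columns]
    if missing:
        raise DataError(f"transition list {path} lacks expected column(s): {missing}")
    return frame.rename(columns=rename)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def load_config(path: str) -> tuple[SelectionConfig, ScheduleConfig]:
    """Load a YAML config with optional ``selection:`` and ``schedule:`` sections."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    unknown = set(raw) - {"selection", "schedule"}
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    selection = _build_config(SelectionConfig, raw.get("selection") or {})
    schedule_raw = dict(raw.get("schedule") or {})
    if "ce_coefficients" in schedule_raw:
        schedule_raw["ce_coefficients"] = {
            int(charge): (float(pair[0]), float(pair[1]))
            for charge, pair in schedule_raw["ce_coefficients"].items()
        }
    schedule = _build_config(ScheduleConfig, schedule_raw)
    return selection, schedule


def _build_config(cls, mapping: Mapping):
    valid = set(cls.__dataclass_fields__)
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    config = cls(**mapping)
    config.validate()
    return config
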