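"""Core domain types, configuration objects and the error taxonomy.

The package works on long-format transition-level quantification tables:
one row per (protein, peptide, precursor charge, product ion, replicate)
with an integrated peak area and an apex retention time.  Most pipeline
stages operate on :class:`pandas.DataFrame` objects carrying the canonical
columns in :data:`REPORT_COLUMNS`; the dataclasses here give the same
records a typed face for construction, validation and export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple


# ---------------------------------------------------------------------------
# Errors.  Exit codes: 2 configuration, 3 data, 4 capacity (used by the CLI).
# ---------------------------------------------------------------------------


class SrmBuilderError(Exception):
    """Base class for all package errors; carries a process exit code."""

    exit_code = 1


class ConfigurationError(SrmBuilderError):
    """Invalid configuration: missing columns, bad thresholds, absent coefficients."""

    exit_code = 2


class DataError(SrmBuilderError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class StateError(DataError):
    """An operation was invoked before its inputs were fully assigned."""


class InsufficientReplicatesError(DataError):
    """Fewer replicate observations than the statistic requires."""


class CalibrationError(DataError):
    """Retention-time calibration could not be fitted."""


class CapacityError(SrmBuilderError):
    """A scheduling capacity constraint cannot be satisfied."""

    exit_code = 4


# ---------------------------------------------------------------------------
# Canonical column names for the long-format transition report.
# ---------------------------------------------------------------------------

REPORT_COLUMNS: Tuple[str, ...] = (
    "protein_id",
    "peptide_seq",
    "precursor_charge",
    "precursor_mz",
    "product_ion",
    "product_mz",
    "replicate_id",
    "area",
    "apex_rt",
)

#: Columns that uniquely identify one row of a report.
KEY_COLUMNS: Tuple[str, ...] = (
    "protein_id",
    "peptide_seq",
    "precursor_charge",
    "product_ion",
    "replicate_id",
)

#: Columns that identify one transition (across replicates).
TRANSITION_KEY: Tuple[str, ...] = (
    "protein_id",
    "peptide_seq",
    "precursor_charge",
    "product_ion",
)

#: Columns that identify one precursor (peptide at one charge state).
PEPTIDE_KEY: Tuple[str, ...] = ("protein_id", "peptide_seq", "precursor_charge")

_NUMERIC_COLUMNS: Tuple[str, ...] = ("precursor_mz", "product_mz", "area", "apex_rt")


@dataclass(frozen=True)
class TransitionRecord:
    """One measured transition in one replicate.

    ``product_ion`` is an ion label such as ``"y7+"`` (series letter,
    ordinal, product charge marks); ``area`` is the integrated peak
    intensity in arbitrary units and ``apex_rt`` the chromatographic peak
    apex in minutes.  Modified peptide sequences are opaque identifiers;
    no masses are recomputed from them.
    """

    protein_id: str
    peptide_seq: str
    precursor_charge: int
    precursor_mz: float
    product_ion: str
    product_mz: float
    replicate_id: str
    area: float
    apex_rt: float

    def validate(self) -> None:
        if not self.protein_id or not self.peptide_seq or not self.product_ion:
            raise DataError(f"empty identifier in record {self!r}")
        if self.precursor_charge < 1:
            raise DataError(f"precursor_charge must be >= 1, got {self.precursor_charge}")
        if not (self.precursor_mz > 0) or not (self.product_mz > 0):
            raise DataError(f"m/z values must be positive in record {self!r}")
        if self.area < 0:
            raise DataError(f"area must be non-negative, got {self.area}")
        if self.apex_rt < 0:
            raise DataError(f"apex_rt must be non-negative, got {self.apex_rt}")


@dataclass
class StandardPeptide:
    """A retention-time standard (e.g. one PRTC peptide).

    ``irt`` is the dimensionless indexed retention time; ``measured_rt``
    (minutes) is filled once the standard has been observed on the LC
    setup being calibrated.  ``transitions`` lists ``(product_ion,
    product_mz)`` pairs so standards can be carried into every exported
    method; ``collision_energy`` is assigned at scheduling time.
    """

    name: str
    irt: float
    measured_rt: Optional[float] = None
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    transitions: list = field(default_factory=list)
    collision_energy: Optional[float] = None

    def validate(self) -> None:
        if not self.name:
            raise DataError("standard peptide with empty name")
        if not math.isfinite(self.irt):
            raise DataError(f"standard {self.name!r} has non-finite iRT")


@dataclass
class SelectionConfig:
    """Thresholds for the quantifiability filter and the ranked selection rules.

    Defaults implement: at least 3 co-eluting interference-free
    transitions, replicate %CV at or below 20, per protein consider the
    top 5 peptides by summed intensity and keep the 2 with the lowest
    %CV, carrying each peptide's 5 most intense clean transitions.
    """

    min_clean_transitions: int = 3
    cv_threshold_pct: float = 20.0
    top_k_peptides_by_intensity: int = 5
    n_peptides_per_protein: int = 2
    n_transitions_per_peptide: int = 5
    require_min_peptides_per_protein: int = 1
    apex_tolerance_min: float = 0.1
    tic_normalize: bool = True
    #: "le" keeps peptides with cv <= threshold, "lt" requires cv < threshold.
    cv_comparison: str = "le"

    def validate(self) -> None:
        for name in (
            "min_clean_transitions",
            "top_k_peptides_by_intensity",
            "n_peptides_per_protein",
            "n_transitions_per_peptide",
            "require_min_peptides_per_protein",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        if not (self.cv_threshold_pct > 0):
            raise ConfigurationError("cv_threshold_pct must be > 0")
        if not (self.apex_tolerance_min > 0):
            raise ConfigurationError("apex_tolerance_min must be > 0")
        if self.cv_comparison not in ("le", "lt"):
            raise ConfigurationError("cv_comparison must be 'le' or 'lt'")


#: Default linear collision-energy ramps per precursor charge,
#: CE(eV) = slope * precursor_mz + intercept.  These are the commonly used
#: triple-quadrupole coefficients; instruments differ, so they are plain
#: configuration, editable from YAML.
DEFAULT_CE_COEFFICIENTS: Mapping[int, Tuple[float, float]] = {
    2: (0.03, 2.905),
    3: (0.038, 2.281),
}


@dataclass
class ScheduleConfig:
    """Scheduled-acquisition parameters for method export.

    ``window_min`` is the full width (minutes) of the retention-time
    window around each target's predicted RT; ``max_concurrent_transitions``
    bounds how many transitions may be open at any instant in one method;
    ``dwell_ms`` is export metadata only.
    """

    window_min: float = 5.0
    max_concurrent_transitions: int = 200
    dwell_ms: float = 10.0
    ce_coefficients: Mapping[int, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CE_COEFFICIENTS)
    )
    gradient_length_min: float = 60.0

    def validate(self) -> None:
        if not (self.window_min > 0):
            raise ConfigurationError("window_min must be > 0")
        if not isinstance(self.max_concurrent_transitions, int) or self.max_concurrent_transitions < 1:
            raise ConfigurationError("max_concurrent_transitions must be an integer >= 1")
        if not (self.dwell_ms > 0):
            raise ConfigurationError("dwell_ms must be > 0")
        if not (self.gradient_length_min > 0):
            raise ConfigurationError("gradient_length_min must be > 0")
        for charge, pair in dict(self.ce_coefficients).items():
            if not isinstance(charge, int) or charge < 1 or len(tuple(pair)) != 2:
                raise ConfigurationError(
                    f"ce_coefficients must map integer charge -> (slope, intercept); got {charge!r}: {pair!r}"
                )


def records_to_frame(records: Sequence[TransitionRecord]):
    """Convert typed records to the canonical report DataFrame."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in records], columns=list(REPORT_COLUMNS))


def frame_to_records(frame) -> list:
    """Convert a canonical report DataFrame to a list of TransitionRecord."""
    return [
        TransitionRecord(
            protein_id=row.protein_id,
            peptide_seq=row.peptide_seq,
            precursor_charge=int(row.precursor_charge),
            precursor_mz=float(row.precursor_mz),
            product_ion=row.product_ion,
            product_mz=float(row.product_mz),
            replicate_id=row.replicate_id,
            area=float(row.area),
            apex_rt=float(row.apex_rt),
        )
        for row in frame.itertuples(index=False)
    ]
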