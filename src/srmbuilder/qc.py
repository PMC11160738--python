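"""Co-elution QC: flag transitions whose peak apex does not co-elute.

In a clean extracted chromatogram all product-ion transitions of a
peptide reach their apex at (nearly) the same retention time.  A
transition whose apex deviates from the peptide's consensus apex carries
signal from another analyte ("interference") and is unusable for a
targeted assay.  The rule implemented here: within one replicate, the
consensus apex is the **median** apex over the peptide's transitions, and
a transition is flagged iff its apex deviates from that median by more
than ``apex_tolerance_min`` minutes.  A transition is *clean* only if it
is unflagged in **every** replicate (strict AND across replicates).

Degenerate cases: a single transition is never flagged (co-elution is
undefined); with two transitions the median is their midpoint, so both
are flagged when they disagree by more than twice the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ConfigurationError, PEPTIDE_KEY, TRANSITION_KEY


@dataclass
class QCResult:
    """Per-transition interference QC.

    Attributes
    ----------
    flags:
        Long table, one row per transition per replicate:
        transition key columns + ``replicate_id`` + boolean ``flagged``.
    transitions:
        One row per transition: key columns, ``n_flagged_replicates`` and
        boolean ``clean`` (unflagged in every replicate).
    clean_counts:
        One row per peptide (precursor): key columns +
        ``clean_transition_count``.
    """

    flags: pd.DataFrame
    transitions: pd.DataFrame
    clean_counts: pd.DataFrame

    def clean_set(self) -> set:
        clean = self.transitions[self.transitions["clean"]]
        return set(map(tuple, clean[list(TRANSITION_KEY)].itertuples(index=False, name=None)))


def flag_interference(apex_rts, apex_tolerance_min: float) -> np.ndarray:
    """Flag the apexes of one peptide in one replicate.

    Returns a boolean array aligned with ``apex_rts``; True marks a
    transition whose apex deviates from the median apex by more than the
    tolerance.  With a single value nothing is flagged.
    """
    if not (apex_tolerance_min > 0):
        raise ConfigurationError("apex_tolerance_min must be > 0")
    apex = np.asarray(apex_rts, dtype=float)
    if apex.size <= 1:
        return np.zeros(apex.shape, dtype=bool)
    return np.abs(apex - np.median(apex)) > apex_tolerance_min


def qc_summary(records: pd.DataFrame, apex_tolerance_min: float) -> QCResult:
    """Run interference QC over a full report.

    The median-deviation flag is evaluated per peptide per replicate;
    flags are then aggregated across replicates with a strict AND
    (``clean`` iff unflagged everywhere) and clean transitions are counted
    per peptide.  Every transition in the report receives a QC record.
    """
    if not (apex_tolerance_min > 0):
        raise ConfigurationError("apex_tolerance_min must be > 0")
    frame = records.copy()
    group_cols = list(PEPTIDE_KEY) + ["replicate_id"]
    median = frame.groupby(group_cols)["apex_rt"].transform("median")
    n_in_group = frame.groupby(group_cols)["apex_rt"].transform("size")
    frame["flagged"] = ((frame["apex_rt"] - median).abs() > apex_tolerance_min) & (n_in_group > 1)

    flags = frame[list(TRANSITION_KEY) + ["replicate_id", "flagged"]].reset_index(drop=True)
    per_transition = (
        flags.groupby(list(TRANSITION_KEY), sort=False)["flagged"]
        .agg(n_flagged_replicates="sum", flagged_any="any")
        .reset_index()
    )
    per_transition["clean"] = ~per_transition.pop("flagged_any")
    per_transition["n_flagged_replicates"] = per_transition["n_flagged_replicates"].astype(int)

    clean_counts = (
        per_transition.groupby(list(PEPTIDE_KEY), sort=False)["clean"]
        .sum()
        .astype(int)
        .rename("clean_transition_count")
        .reset_index()
    )
    return QCResult(flags=flags, transitions=per_transition, clean_counts=clean_counts)


def qc_table(result: QCResult) -> pd.DataFrame:
    """Wide export table: per-replicate flags, clean status, per-peptide clean count."""
    wide = result.flags.pivot_table(
        index=list(TRANSITION_KEY),
        columns="replicate_id",
        values="flagged",
        aggfunc="first",
    )
    wide.columns = [f"flagged_{c}" for c in wide.columns]
    wide = wide.reset_index()
    wide = wide.merge(result.transitions[list(TRANSITION_KEY) + ["clean"]], on=list(TRANSITION_KEY))
    wide = wide.merge(result.clean_counts, on=list(PEPTIDE_KEY))
    return wide
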