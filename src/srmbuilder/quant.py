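"""Replicate normalization and per-peptide quantitative summaries.

The stability screen of the workflow: for every peptide, sum the areas of
its top-N interference-free transitions within each replicate (the same
transition set in every replicate, chosen on mean area), and compute the
percent coefficient of variation (%CV, sample SD over mean) of those
per-replicate sums.  Replicates are optionally brought onto a common
scale first by total-ion-current (TIC) normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .model import (
    DataError,
    InsufficientReplicatesError,
    PEPTIDE_KEY,
)
from .qc import QCResult


@dataclass(frozen=True)
class TransitionRank:
    """A clean transition with its mean area across replicates (rank 1 = most intense)."""

    product_ion: str
    product_mz: float
    mean_area: float
    rank: int


@dataclass
class PeptideQuantSummary:
    """Quantitative summary for one peptide (one precursor charge state).

    ``summed_area_per_replicate`` sums one fixed set of transitions — the
    top ``n`` clean transitions by mean area — in every replicate.
    ``cv_pct`` is the %CV of those sums; peptides observed in fewer than
    two replicates are marked non-quantifiable (``cv_pct`` is NaN).
    """

    protein_id: str
    peptide_seq: str
    precursor_charge: int
    precursor_mz: float
    clean_transition_count: int
    summed_area_per_replicate: Dict[str, float] = field(default_factory=dict)
    mean_summed_area: float = float("nan")
    cv_pct: float = float("nan")
    quantifiable: bool = False
    transition_intensity_ranks: List[TransitionRank] = field(default_factory=list)

    @property
    def peptide_key(self):
        return (self.protein_id, self.peptide_seq, self.precursor_charge)


def tic_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Scale each replicate so all replicates have equal total area.

    normalized area = area × (mean over replicates of total area) / (own
    replicate's total area); after normalization every replicate's total
    equals the mean of the original totals.

    Raises
    ------
    DataError
        If any replicate has zero total area (names the replicate).
    """
    totals = records.groupby("replicate_id")["area"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"replicate {zero.index[0]!r} has non-positive total area")
    factors = totals.mean() / totals
    out = records.copy()
    out["area"] = out["area"] * out["replicate_id"].map(factors)
    return out


def percent_cv(values: Sequence[float]) -> float:
    """Percent coefficient of variation: 100 × sample SD (n−1) / mean.

    Requires at least two finite values with a positive mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientReplicatesError(
            f"%CV needs at least 2 values, got {arr.size}"
        )
    if not np.isfinite(arr).all():
        raise DataError("%CV input contains non-finite values")
    mean = arr.mean()
    if mean <= 0:
        raise DataError(f"%CV undefined for non-positive mean ({mean})")
    return float(100.0 * arr.std(ddof=1) / mean)


def summarize_peptides(
    records: pd.DataFrame,
    qc: QCResult,
    n_transitions_for_sum: int = 5,
) -> List[PeptideQuantSummary]:
    """Build a :class:`PeptideQuantSummary` for every peptide in the report.

    Clean transitions are ranked by their mean area across replicates
    (ties broken by ascending product m/z, then ion label, for
    reproducibility); the top ``min(n, clean count)`` of them — one fixed
    set — are summed within each replicate, and %CV is computed on those
    sums.  Records should already be TIC-normalized if normalization is
    wanted.
    """
    clean_keys = qc.clean_set()
    summaries: List[PeptideQuantSummary] = []
    for key, group in records.groupby(list(PEPTIDE_KEY), sort=True):
        protein_id, peptide_seq, charge = key
        precursor_mz = float(group["precursor_mz"].iloc[0])
        clean_mask = [
            (protein_id, peptide_seq, charge, ion) in clean_keys
            for ion in group["product_ion"]
        ]
        clean_rows = group[np.asarray(clean_mask)]
        summary = PeptideQuantSummary(
            protein_id=protein_id,
            peptide_seq=peptide_seq,
            precursor_charge=int(charge),
            precursor_mz=precursor_mz,
            clean_transition_count=int(clean_rows["product_ion"].nunique()),
        )
        if len(clean_rows):
            per_transition = (
                clean_rows.groupby(["product_ion", "product_mz"])["area"]
                .mean()
                .reset_index()
                .sort_values(
                    by=["area", "product_mz", "product_ion"],
                    ascending=[False, True, True],
                    kind="mergesort",
                )
                .reset_index(drop=True)
            )
            summary.transition_intensity_ranks = [
                TransitionRank(
                    product_ion=str(row.product_ion),
                    product_mz=float(row.product_mz),
                    mean_area=float(row.area),
                    rank=i + 1,
                )
                for i, row in enumerate(per_transition.itertuples(index=False))
            ]
            top = {
                t.product_ion
                for t in summary.transition_intensity_ranks[:n_transitions_for_sum]
            }
            top_rows = clean_rows[clean_rows["product_ion"].isin(top)]
            sums = top_rows.groupby("replicate_id")["area"].sum()
            summary.summed_area_per_replicate = {
                str(rep): float(v) for rep, v in sums.items()
            }
            if len(sums):
                summary.mean_summed_area = float(sums.mean())
            if len(sums) >= 2 and sums.mean() > 0:
                summary.cv_pct = percent_cv(sums.to_numpy())
                summary.quantifiable = True
        summaries.append(summary)
    return summaries


def summaries_to_frame(summaries: Sequence[PeptideQuantSummary]) -> pd.DataFrame:
    """Flatten summaries for CSV export (per-replicate sums as JSON-ish columns)."""
    rows = []
    for s in summaries:
        row = {
            "protein_id": s.protein_id,
            "peptide_seq": s.peptide_seq,
            "precursor_charge": s.precursor_charge,
            "precursor_mz": s.precursor_mz,
            "clean_transition_count": s.clean_transition_count,
            "mean_summed_area": s.mean_summed_area,
            "cv_pct": s.cv_pct,
            "quantifiable": s.quantifiable,
        }
        for rep, value in sorted(s.summed_area_per_replicate.items()):
            row[f"summed_area_{rep}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
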