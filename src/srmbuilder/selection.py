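"""Ranked proxy-peptide and transition selection, plus assay-overlap reports.

The selection rules, applied per protein to peptides that passed the
quantifiability filter (enough clean co-eluting transitions, %CV at or
below threshold):

1. when a protein has more candidate peptides than will be kept, only the
   ``top_k_peptides_by_intensity`` (default 5) peptides by mean summed
   area are considered;
2. from those, the ``n_peptides_per_protein`` (default 2) with the lowest
   %CV are selected;
3. each selected peptide carries its ``n_transitions_per_peptide``
   (default 5) most intense clean transitions, in intensity-rank order.

All ties break lexicographically (peptide sequence, then product m/z) so
identical inputs always yield identical assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import math

from .model import SelectionConfig
from .quant import PeptideQuantSummary

#: Machine-readable reasons in the dropped-protein log.
REASON_TOO_FEW_CLEAN = "too_few_clean_transitions"
REASON_CV = "cv_above_threshold"
REASON_TOO_FEW_PEPTIDES = "too_few_qualifying_peptides"
REASON_NOT_QUANTIFIABLE = "too_few_replicates"


@dataclass(frozen=True)
class AssayTransition:
    product_ion: str
    product_mz: float
    rank: int


@dataclass
class AssayTarget:
    """A selected proxy peptide with its ranked transitions.

    ``irt`` is the dimensionless library retention index carried over
    from the DIA data; ``predicted_rt``/``window``/``collision_energy``
    are filled in at scheduling time.
    """

    protein_id: str
    peptide_seq: str
    precursor_charge: int
    precursor_mz: float
    transitions: List[AssayTransition]
    cv_pct: float = float("nan")
    mean_summed_area: float = float("nan")
    irt: Optional[float] = None
    predicted_rt: Optional[float] = None
    window: Optional[Tuple[float, float]] = None
    collision_energy: Optional[float] = None


@dataclass
class SelectionResult:
    targets: List[AssayTarget]
    #: protein_id -> reason, for proteins dropped at the selection stage
    dropped: Dict[str, str] = field(default_factory=dict)


@dataclass
class OverlapReport:
    """Comparison of a selected assay against a reference peptide list."""

    n_reference_peptides: int
    n_selected_peptides: int
    n_shared: int
    pct_selected_unique: float
    proteins_with_identical_selection: List[str]
    proteins_with_no_overlap: List[str]


def collapse_charge_states(
    summaries: Sequence[PeptideQuantSummary],
) -> List[PeptideQuantSummary]:
    """Keep one precursor charge per peptide sequence: the more intense one.

    Peptides, not precursors, are the selection unit; when the same
    sequence was measured at several charge states the one with the
    larger mean summed area is kept (ties: lower charge).
    """
    best: Dict[Tuple[str, str], PeptideQuantSummary] = {}
    for summary in summaries:
        key = (summary.protein_id, summary.peptide_seq)
        current = best.get(key)
        if current is None:
            best[key] = summary
            continue
        a = summary.mean_summed_area
        b = current.mean_summed_area
        a = a if math.isfinite(a) else float("-inf")
        b = b if math.isfinite(b) else float("-inf")
        if (a, -summary.precursor_charge) > (b, -current.precursor_charge):
            best[key] = summary
    return sorted(best.values(), key=lambda s: s.peptide_key)


def filter_quantifiable(
    summaries: Sequence[PeptideQuantSummary], config: SelectionConfig
) -> Tuple[List[PeptideQuantSummary], List[Tuple[PeptideQuantSummary, str]]]:
    """Apply the quantifiability filter.

    Keeps peptides with ``clean_transition_count >= min_clean_transitions``
    and %CV within ``cv_threshold_pct`` (``<=`` by default, ``<`` when
    ``cv_comparison == "lt"``).  Returns (kept, rejected-with-reason).
    """
    kept: List[PeptideQuantSummary] = []
    rejected: List[Tuple[PeptideQuantSummary, str]] = []
    for summary in summaries:
        if summary.clean_transition_count < config.min_clean_transitions:
            rejected.append((summary, REASON_TOO_FEW_CLEAN))
            continue
        if not summary.quantifiable:
            rejected.append((summary, REASON_NOT_QUANTIFIABLE))
            continue
        if config.cv_comparison == "lt":
            ok = summary.cv_pct < config.cv_threshold_pct
        else:
            ok = summary.cv_pct <= config.cv_threshold_pct
        if not ok:
            rejected.append((summary, REASON_CV))
            continue
        kept.append(summary)
    return kept, rejected


def _target_from_summary(
    summary: PeptideQuantSummary, n_transitions: int
) -> AssayTarget:
    transitions = [
        AssayTransition(t.product_ion, t.product_mz, t.rank)
        for t in summary.transition_intensity_ranks[:n_transitions]
    ]
    return AssayTarget(
        protein_id=summary.protein_id,
        peptide_seq=summary.peptide_seq,
        precursor_charge=summary.precursor_charge,
        precursor_mz=summary.precursor_mz,
        transitions=transitions,
        cv_pct=summary.cv_pct,
        mean_summed_area=summary.mean_summed_area,
    )


def select_assay(
    qualifying: Sequence[PeptideQuantSummary], config: SelectionConfig
) -> SelectionResult:
    """Apply the per-protein ranked selection rules to qualifying peptides.

    Proteins with fewer than ``require_min_peptides_per_protein``
    qualifying peptides are dropped and listed in the result's
    ``dropped`` log.
    """
    by_protein: Dict[str, List[PeptideQuantSummary]] = {}
    for summary in qualifying:
        by_protein.setdefault(summary.protein_id, []).append(summary)

    result = SelectionResult(targets=[])
    for protein_id in sorted(by_protein):
        candidates = by_protein[protein_id]
        if len(candidates) < config.require_min_peptides_per_protein:
            result.dropped[protein_id] = REASON_TOO_FEW_PEPTIDES
            continue
        if len(candidates) > config.n_peptides_per_protein:
            pool = sorted(
                candidates,
                key=lambda s: (-s.mean_summed_area, s.peptide_seq),
            )[: config.top_k_peptides_by_intensity]
            chosen = sorted(pool, key=lambda s: (s.cv_pct, s.peptide_seq))[
                : config.n_peptides_per_protein
            ]
        else:
            chosen = list(candidates)
        chosen.sort(key=lambda s: s.peptide_key)
        for summary in chosen:
            result.targets.append(
                _target_from_summary(summary, config.n_transitions_per_peptide)
            )
    return result


def build_targets(
    summaries: Sequence[PeptideQuantSummary], config: SelectionConfig
) -> Tuple[SelectionResult, List[PeptideQuantSummary], List[Tuple[PeptideQuantSummary, str]]]:
    """Charge collapse → quantifiability filter → ranked selection.

    Returns the selection result (with a complete dropped-protein log,
    including proteins whose peptides all failed the filter, attributed
    to the dominant per-peptide failure reason), the qualifying peptides,
    and the per-peptide filter rejections.
    """
    collapsed = collapse_charge_states(summaries)
    kept, rejected = filter_quantifiable(collapsed, config)
    result = select_assay(kept, config)

    qualifying_proteins = {s.protein_id for s in kept}
    failed_by_protein: Dict[str, List[str]] = {}
    for summary, reason in rejected:
        failed_by_protein.setdefault(summary.protein_id, []).append(reason)
    for protein_id, reasons in sorted(failed_by_protein.items()):
        if protein_id in qualifying_proteins or protein_id in result.dropped:
            continue
        # all of this protein's peptides failed the filter
        for reason in (REASON_TOO_FEW_CLEAN, REASON_CV, REASON_NOT_QUANTIFIABLE):
            if reason in reasons:
                result.dropped[protein_id] = reason
                break
    return result, kept, rejected


def compare_to_reference(
    selected: Sequence[AssayTarget],
    reference: Sequence[Tuple[str, str, Optional[int]]],
    sequence_only: bool = False,
) -> OverlapReport:
    """Compare selected peptides against a reference peptide list.

    ``reference`` holds (protein_id, peptide_seq, precursor_charge)
    triples; charge may be None.  Peptide identity is exact modified
    sequence + charge, or sequence only when ``sequence_only`` is set (or
    the reference carries no charges).
    """

    def _pep_key(seq: str, charge: Optional[int]):
        return seq if sequence_only or charge is None else (seq, int(charge))

    selected_keys = {
        _pep_key(t.peptide_seq, t.precursor_charge) for t in selected
    }
    reference_keys = {_pep_key(seq, charge) for _, seq, charge in reference}
    shared = selected_keys & reference_keys

    selected_by_protein: Dict[str, set] = {}
    for t in selected:
        selected_by_protein.setdefault(t.protein_id, set()).add(
            _pep_key(t.peptide_seq, t.precursor_charge)
        )
    reference_by_protein: Dict[str, set] = {}
    for protein_id, seq, charge in reference:
        reference_by_protein.setdefault(protein_id, set()).add(_pep_key(seq, charge))

    common_proteins = sorted(set(selected_by_protein) & set(reference_by_protein))
    identical = [
        p for p in common_proteins if selected_by_protein[p] == reference_by_protein[p]
    ]
    no_overlap = [
        p
        for p in common_proteins
        if not (selected_by_protein[p] & reference_by_protein[p])
    ]

    n_selected = len(selected_keys)
    n_shared = len(shared)
    pct_unique = 100.0 * (n_selected - n_shared) / n_selected if n_selected else 0.0
    return OverlapReport(
        n_reference_peptides=len(reference_keys),
        n_selected_peptides=n_selected,
        n_shared=n_shared,
        pct_selected_unique=pct_unique,
        proteins_with_identical_selection=identical,
        proteins_with_no_overlap=no_overlap,
    )
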