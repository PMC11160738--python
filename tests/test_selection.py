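import itertools

import numpy as np
import pytest

import srmbuilder as sb
from srmbuilder.model import SelectionConfig
from srmbuilder.selection import (
    REASON_CV,
    REASON_TOO_FEW_CLEAN,
    REASON_TOO_FEW_PEPTIDES,
    collapse_charge_states,
    compare_to_reference,
    filter_quantifiable,
    select_assay,
)

from conftest import make_summary


def test_filter_thresholds():
    config = SelectionConfig()
    kept, rejected = filter_quantifiable(
        [
            make_summary(seq="AK", clean=2),
            make_summary(seq="BK", clean=5, cv=19.9),
            make_summary(seq="CK", clean=5, cv=20.0),
            make_summary(seq="DK", clean=5, cv=20.1),
        ],
        config,
    )
    assert {s.peptide_seq for s in kept} == {"BK", "CK"}  # <=20 keeps cv == 20
    reasons = {s.peptide_seq: r for s, r in rejected}
    assert reasons == {"AK": REASON_TOO_FEW_CLEAN, "DK": REASON_CV}


def test_filter_strict_comparison_mode():
    config = SelectionConfig(cv_comparison="lt")
    kept, _ = filter_quantifiable([make_summary(seq="CK", clean=5, cv=20.0)], config)
    assert kept == []


def test_filter_min_clean_five():
    config = SelectionConfig(min_clean_transitions=5)
    kept, _ = filter_quantifiable(
        [make_summary(seq="AK", clean=5), make_summary(seq="BK", clean=4)], config
    )
    assert {s.peptide_seq for s in kept} == {"AK"}


def test_raising_cv_threshold_is_monotone():
    rng = np.random.default_rng(1)
    summaries = [
        make_summary(seq=f"PEP{i}K", clean=5, cv=float(rng.uniform(0, 60)))
        for i in range(40)
    ]
    previous = set()
    for threshold in (5.0, 10.0, 20.0, 40.0, 80.0):
        kept, _ = filter_quantifiable(
            summaries, SelectionConfig(cv_threshold_pct=threshold)
        )
        current = {s.peptide_seq for s in kept}
        assert previous <= current
        previous = current


def test_selects_lowest_cv_among_top_intensity_pool():
    """With 7 candidates the pool is the top 5 by intensity; the 2 lowest-CV
    members of that pool win even if they are intensity ranks 4 and 5."""
    summaries = [
        make_summary(seq=f"PEP{i}K", area=1000.0 - 100 * i, cv=cv)
        for i, cv in enumerate([10.0, 9.0, 8.0, 2.0, 1.0, 0.5, 0.1])
    ]
    result = select_assay(summaries, SelectionConfig())
    assert {t.peptide_seq for t in result.targets} == {"PEP3K", "PEP4K"}


def test_exactly_two_candidates_both_selected():
    summaries = [
        make_summary(seq="AK", area=10.0, cv=50.0, clean=5),
        make_summary(seq="BK", area=5000.0, cv=0.5, clean=5),
    ]
    # the intensity pool rule only kicks in for > n_peptides_per_protein candidates
    result = select_assay(summaries, SelectionConfig(cv_threshold_pct=60))
    assert {t.peptide_seq for t in result.targets} == {"AK", "BK"}


def test_protein_below_min_peptides_dropped_with_reason():
    result = select_assay(
        [make_summary(seq="AK")],
        SelectionConfig(require_min_peptides_per_protein=2),
    )
    assert result.targets == []
    assert result.dropped == {"PROT001": REASON_TOO_FEW_PEPTIDES}


def test_targets_carry_top_transitions_in_rank_order():
    (target,) = select_assay(
        [make_summary(seq="AK", n_rank_transitions=7)],
        SelectionConfig(n_transitions_per_peptide=5),
    ).targets
    assert [t.rank for t in target.transitions] == [1, 2, 3, 4, 5]


def test_charge_collapse_keeps_more_intense_precursor():
    collapsed = collapse_charge_states(
        [
            make_summary(seq="AK", charge=2, area=100.0),
            make_summary(seq="AK", charge=3, area=900.0),
            make_summary(seq="BK", charge=2, area=50.0),
        ]
    )
    by_seq = {s.peptide_seq: s.precursor_charge for s in collapsed}
    assert by_seq == {"AK": 3, "BK": 2}


def test_tie_break_is_lexicographic():
    summaries = [
        make_summary(seq=seq, area=100.0, cv=5.0) for seq in ("ZK", "AK", "MK")
    ]
    result = select_assay(summaries, SelectionConfig())
    assert [t.peptide_seq for t in result.targets] == ["AK", "MK"]


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle
# ---------------------------------------------------------------------------


def oracle_select(peptides, config):
    """Independent evaluation of the selection rules by enumeration.

    peptides: list of (seq, mean_area, cv).  Returns the selected set of
    sequences, minimizing (sum of CVs, lexicographic sequence tuple) over
    all subsets of the intensity pool.
    """
    if len(peptides) > config.n_peptides_per_protein:
        pool = sorted(peptides, key=lambda p: (-p[1], p[0]))[
            : config.top_k_peptides_by_intensity
        ]
        size = min(config.n_peptides_per_protein, len(pool))
        best = min(
            itertools.combinations(pool, size),
            key=lambda combo: (sum(p[2] for p in combo), tuple(sorted(p[0] for p in combo))),
        )
        return {p[0] for p in best}
    return {p[0] for p in peptides}


def random_instance(rng, quantized_ties=False):
    summaries = []
    n_proteins = int(rng.integers(1, 11))
    for p in range(n_proteins):
        n_pep = int(rng.integers(1, 9))
        for q in range(n_pep):
            area = float(rng.uniform(10, 1000))
            cv = float(rng.uniform(0, 20))
            if quantized_ties:
                area, cv = round(area, -2), round(cv)
            summaries.append(
                make_summary(
                    protein=f"PR{p:02d}",
                    seq=f"PEP{p:02d}X{q}K",
                    area=area,
                    cv=cv,
                )
            )
    return summaries


@pytest.mark.parametrize("quantized_ties", [False, True])
def test_selection_matches_enumeration_oracle(quantized_ties):
    rng = np.random.default_rng(2024 + quantized_ties)
    config = SelectionConfig()
    for _ in range(300):
        summaries = random_instance(rng, quantized_ties)
        result = select_assay(summaries, config)
        selected = {}
        for t in result.targets:
            selected.setdefault(t.protein_id, set()).add(t.peptide_seq)
        by_protein = {}
        for s in summaries:
            by_protein.setdefault(s.protein_id, []).append(
                (s.peptide_seq, s.mean_summed_area, s.cv_pct)
            )
        for protein, peps in by_protein.items():
            assert selected.get(protein, set()) == oracle_select(peps, config)


def test_selection_is_deterministic():
    rng = np.random.default_rng(7)
    summaries = random_instance(rng)
    config = SelectionConfig()
    a = select_assay(list(summaries), config)
    b = select_assay(list(reversed(summaries)), config)
    assert [(t.protein_id, t.peptide_seq) for t in a.targets] == [
        (t.protein_id, t.peptide_seq) for t in b.targets
    ]


def test_planted_good_pair_recovered_over_seeds():
    """Two stable high-intensity peptides among unstable decoys are always selected."""
    config = SelectionConfig()
    hits = trials = 0
    for seed in range(20):
        rep = sb.generate_report(
            sb.SyntheticConfig(
                seed=seed,
                n_proteins=5,
                peptides_per_protein=(4, 4),
                transitions_per_peptide=(6, 6),
                noise_cv=0.04,
                frac_unstable_peptides=0.0,
                frac_interfered_transitions=0.0,
                rt_model=(0.5, 5.0, 0.01),
            )
        )
        # plant: mark 2 of each protein's 4 peptides unstable by inflating rep3
        truth = rep.truth_peptides.sort_values(["protein_id", "peptide_seq"])
        report = rep.report
        planted = {}
        for protein, group in truth.groupby("protein_id"):
            decoys = list(group["peptide_seq"].iloc[:2])
            planted[protein] = set(group["peptide_seq"].iloc[2:])
            mask = report["peptide_seq"].isin(decoys) & (report["replicate_id"] == "rep3")
            report.loc[mask, "area"] *= 3.0
        qc = sb.qc_summary(report, config.apex_tolerance_min)
        summaries = sb.summarize_peptides(report, qc, 5)
        result = select_assay(filter_quantifiable(summaries, config)[0], config)
        selected = {}
        for t in result.targets:
            selected.setdefault(t.protein_id, set()).add(t.peptide_seq)
        for protein, expected in planted.items():
            trials += 1
            hits += selected.get(protein, set()) == expected
    assert hits / trials >= 0.99


# ---------------------------------------------------------------------------
# Overlap report
# ---------------------------------------------------------------------------


def _targets(pairs):
    return select_assay(
        [make_summary(protein=p, seq=s) for p, s in pairs],
        SelectionConfig(n_peptides_per_protein=5),
    ).targets


def test_overlap_identity():
    targets = _targets([("P1", "AK"), ("P1", "BK"), ("P2", "CK")])
    reference = [(t.protein_id, t.peptide_seq, t.precursor_charge) for t in targets]
    report = compare_to_reference(targets, reference)
    assert report.pct_selected_unique == 0.0
    assert report.n_shared == 3
    assert report.proteins_with_identical_selection == ["P1", "P2"]
    assert report.proteins_with_no_overlap == []


def test_overlap_disjoint():
    targets = _targets([("P1", "AK"), ("P2", "CK")])
    report = compare_to_reference(targets, [("P1", "XK", 2), ("P2", "YK", 2)])
    assert report.pct_selected_unique == 100.0
    assert report.proteins_with_no_overlap == ["P1", "P2"]
    assert report.proteins_with_identical_selection == []


def test_overlap_percentage_arithmetic():
    targets = _targets([(f"P{i}", f"PEP{i:03d}K") for i in range(200)])
    reference = [
        (t.protein_id, t.peptide_seq, t.precursor_charge) for t in targets[:50]
    ]
    report = compare_to_reference(targets, reference)
    assert report.n_selected_peptides == 200
    assert report.n_shared == 50
    assert report.pct_selected_unique == pytest.approx(75.0)
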