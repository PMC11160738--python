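import numpy as np
import pandas as pd
import pytest

import srmbuilder as sb
from srmbuilder.model import REPORT_COLUMNS
from srmbuilder.quant import PeptideQuantSummary, TransitionRank


def make_report(rows):
    """Build a canonical report DataFrame from row tuples."""
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def tiny_report_rows(n_proteins=1, n_peptides=2, n_transitions=4, n_replicates=3):
    """A fully clean, noiseless nested report for parser/contract tests."""
    rows = []
    for p in range(n_proteins):
        for q in range(n_peptides):
            seq = f"PEPTIDE{p}{q}K"
            for t in range(n_transitions):
                for r in range(n_replicates):
                    rows.append(
                        (
                            f"PROT{p:03d}",
                            seq,
                            2,
                            500.0 + 10 * q,
                            f"y{t + 3}+",
                            600.0 + 25 * t,
                            f"rep{r + 1}",
                            1000.0 * (0.7**t),
                            20.0 + q,
                        )
                    )
    return rows


@pytest.fixture
def tiny_report():
    return make_report(tiny_report_rows())


def make_summary(
    protein="PROT001",
    seq="AAAAK",
    charge=2,
    mz=500.0,
    clean=6,
    area=1e6,
    cv=5.0,
    n_rank_transitions=6,
):
    """A hand-built PeptideQuantSummary for selection-rule tests."""
    ranks = [
        TransitionRank(f"y{n_rank_transitions + 2 - i}+", 600.0 + 25 * i, area * 0.7**i, i + 1)
        for i in range(n_rank_transitions)
    ]
    return PeptideQuantSummary(
        protein_id=protein,
        peptide_seq=seq,
        precursor_charge=charge,
        precursor_mz=mz,
        clean_transition_count=clean,
        summed_area_per_replicate={"rep1": area, "rep2": area, "rep3": area},
        mean_summed_area=area,
        cv_pct=cv,
        quantifiable=True,
        transition_intensity_ranks=ranks,
    )


@pytest.fixture(scope="session")
def pain_panel():
    """Pain-panel preset report plus the built selection, shared across tests."""
    rep = sb.generate_report(sb.preset_pain_panel(7))
    config = sb.SelectionConfig(
        min_clean_transitions=5,
        n_peptides_per_protein=2,
        require_min_peptides_per_protein=2,
        n_transitions_per_peptide=5,
    )
    qc = sb.qc_summary(rep.report, config.apex_tolerance_min)
    summaries = sb.summarize_peptides(
        sb.tic_normalize(rep.report), qc, config.n_transitions_per_peptide
    )
    result, kept, rejected = sb.build_targets(summaries, config)
    return {
        "report": rep,
        "config": config,
        "qc": qc,
        "summaries": summaries,
        "result": result,
        "kept": kept,
        "rejected": rejected,
    }


def grid_concurrency(targets, standards=(), step=0.01, t_max=60.0):
    """Independent dense-grid count of concurrent transitions (oracle)."""
    times = np.arange(0.0, t_max + step, step)
    counts = np.full(times.shape, sum(len(s.transitions) for s in standards), dtype=int)
    for target in targets:
        start, end = target.window
        counts += ((times >= start) & (times < end)) * len(target.transitions)
    return int(counts.max())
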