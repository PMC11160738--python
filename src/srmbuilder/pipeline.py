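"""End-to-end orchestration: build an assay from reports, then schedule it.

``build_assay`` chains QC → normalization → peptide summaries → ranked
selection and writes the assay table, the dropped-protein log and a run
manifest.  ``schedule`` chains RT calibration → window assignment →
collision energies → capacity partitioning and writes one transition
list per method plus a schedule report.  Both are pure functions of
(inputs, config): rerunning with the same inputs reproduces the same
outputs (manifests differ only in timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .io import (
    ReportReadResult,
    load_config,
    read_assay,
    read_standards,
    read_transition_report,
    write_assay,
    write_transition_list,
)
from .model import (
    ConfigurationError,
    DataError,
    PEPTIDE_KEY,
    ScheduleConfig,
    SelectionConfig,
    StateError,
)
from .qc import qc_summary, qc_table
from .quant import summaries_to_frame, summarize_peptides, tic_normalize
from .scheduling import (
    assign_collision_energies,
    assign_windows,
    calibrate_rt,
    collision_energy,
    partition_methods,
)
from .selection import AssayTarget, build_targets

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    tool: str = "srmbuilder"
    version: str = __version__
    created: str = ""
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)
    stages: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def write(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        payload["created"] = datetime.now(timezone.utc).isoformat()
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, default=str)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_reports(report_paths: Sequence[str], column_map=None) -> ReportReadResult:
    parts = [read_transition_report(p, column_map) for p in report_paths]
    records = pd.concat([p.records for p in parts], ignore_index=True)
    rejected = pd.concat([p.rejected for p in parts], ignore_index=True)
    return ReportReadResult(records=records, rejected=rejected)


@dataclass
class BuildAssayResult:
    targets: List[AssayTarget]
    manifest: RunManifest
    dropped: Dict[str, str]
    assay_path: Optional[str] = None


def build_assay(
    report_paths: Sequence[str],
    config: SelectionConfig,
    out_dir: Optional[str] = None,
    standards_path: Optional[str] = None,
    column_map=None,
    seed: Optional[int] = None,
) -> BuildAssayResult:
    """Run QC, quantification and selection over one or more replicate reports.

    When a standards file with measured retention times is given, each
    target is additionally assigned a library iRT by inverting the
    calibration fitted on the standards, which later scheduling re-projects
    onto the SRM gradient.  Writes ``assay.csv``, ``peptide_summary.csv``,
    ``qc_table.csv``, ``dropped_proteins.csv`` and ``manifest.json`` into
    ``out_dir`` when given.
    """
    config.validate()
    result = _read_reports(report_paths, column_map)
    records = result.records
    if records["replicate_id"].nunique() < 2:
        raise DataError("need at least 2 replicates to assess peptide stability")

    manifest = RunManifest(seed=seed, config={"selection": dataclasses.asdict(config)})
    for path in report_paths:
        manifest.inputs[os.path.abspath(path)] = _digest(path)

    qc = qc_summary(records, config.apex_tolerance_min)
    quant_records = tic_normalize(records) if config.tic_normalize else records
    summaries = summarize_peptides(
        quant_records, qc, n_transitions_for_sum=config.n_transitions_per_peptide
    )
    selection, qualifying, rejected = build_targets(summaries, config)

    if standards_path is not None:
        standards = read_standards(standards_path)
        manifest.inputs[os.path.abspath(standards_path)] = _digest(standards_path)
        calibration = calibrate_rt(standards)
        apex_by_peptide = records.groupby(list(PEPTIDE_KEY))["apex_rt"].median()
        for target in selection.targets:
            median_rt = float(
                apex_by_peptide[(target.protein_id, target.peptide_seq, target.precursor_charge)]
            )
            target.irt = calibration.invert(median_rt)

    manifest.stages = {
        "input_rows": int(len(records)),
        "rejected_rows": int(len(result.rejected)),
        "detected_peptides": int(records.groupby(list(PEPTIDE_KEY)).ngroups),
        "detected_proteins": int(records["protein_id"].nunique()),
        "qualifying_peptides": len(qualifying),
        "qualifying_proteins": len({s.protein_id for s in qualifying}),
        "selected_peptides": len(selection.targets),
        "selected_transitions": sum(len(t.transitions) for t in selection.targets),
        "dropped_proteins": len(selection.dropped),
    }
    for protein_id, reason in selection.dropped.items():
        logger.info("dropped protein %s: %s", protein_id, reason)

    assay_path = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        assay_path = os.path.join(out_dir, "assay.csv")
        write_assay(selection.targets, assay_path)
        summaries_to_frame(summaries).to_csv(
            os.path.join(out_dir, "peptide_summary.csv"), index=False
        )
        qc_table(qc).to_csv(os.path.join(out_dir, "qc_table.csv"), index=False)
        pd.DataFrame(
            sorted(selection.dropped.items()), columns=["protein_id", "reason"]
        ).to_csv(os.path.join(out_dir, "dropped_proteins.csv"), index=False)
        manifest.write(os.path.join(out_dir, "manifest.json"))
    return BuildAssayResult(
        targets=selection.targets,
        manifest=manifest,
        dropped=selection.dropped,
        assay_path=assay_path,
    )


@dataclass
class ScheduleResult:
    methods: list
    manifest: RunManifest
    method_paths: List[str]
    report: pd.DataFrame


def schedule(
    assay_path: str,
    standards_path: str,
    config: ScheduleConfig,
    out_dir: Optional[str] = None,
    dialect: str = "instrument",
) -> ScheduleResult:
    """Schedule an assay: calibrate → windows → CE → partition → export."""
    config.validate()
    targets = read_assay(assay_path)
    if not targets:
        raise DataError(f"assay {assay_path} contains no targets")
    missing_irt = [t for t in targets if t.irt is None]
    if missing_irt:
        raise StateError(
            f"{len(missing_irt)} assay target(s) lack iRT values; rebuild the assay "
            "with a standards file so scheduling can predict retention times"
        )
    standards = read_standards(standards_path)
    calibration = calibrate_rt(standards)
    warnings = assign_windows(targets, calibration, config)
    for message in warnings:
        logger.warning("out-of-gradient target: %s", message)
    assign_collision_energies(targets, config)
    for std in standards:
        if std.precursor_mz is not None and std.precursor_charge is not None:
            std.collision_energy = collision_energy(
                std.precursor_mz, std.precursor_charge, config.ce_coefficients
            )
    methods = partition_methods(targets, standards, config)

    manifest = RunManifest(
        config={"schedule": {**dataclasses.asdict(config), "ce_coefficients": {
            str(k): list(v) for k, v in config.ce_coefficients.items()}}},
        inputs={
            os.path.abspath(assay_path): _digest(assay_path),
            os.path.abspath(standards_path): _digest(standards_path),
        },
        warnings=list(warnings),
        stages={
            "targets": len(targets),
            "standards": len(standards),
            "methods": len(methods),
            "calibration_n": calibration.n_standards,
        },
    )

    rows = []
    for method in methods:
        rts = [t.predicted_rt for t in method.targets]
        rows.append(
            {
                "method": method.index,
                "n_targets": len(method.targets),
                "n_transitions": method.n_transitions,
                "peak_concurrency": method.peak_concurrency,
                "peak_time_min": round(method.peak_time, 2),
                "rt_start_min": round(min(rts), 2) if rts else None,
                "rt_end_min": round(max(rts), 2) if rts else None,
            }
        )
    report = pd.DataFrame(rows)

    method_paths: List[str] = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        method_paths = write_transition_list(methods, dialect, out_dir)
        report.to_csv(os.path.join(out_dir, "schedule_report.csv"), index=False)
        manifest.write(os.path.join(out_dir, "manifest.json"))
    return ScheduleResult(
        methods=methods, manifest=manifest, method_paths=method_paths, report=report
    )
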