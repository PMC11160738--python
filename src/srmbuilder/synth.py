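"""Seeded synthetic transition reports with planted ground truth.

The generator emulates what replicate narrow-window DIA experiments hand
to this pipeline: proteins × peptides × product-ion transitions × (3)
replicates, lognormal peptide abundances, a geometric decay of transition
intensities over rank, multiplicative replicate-to-replicate noise,
planted interfered transitions (apex shifted off the co-elution
consensus), planted unstable peptides (inflated replicate scatter), and a
linear iRT → RT relationship with jitter.

Two planting choices matter for interpretation (see docs/methods.md):

* replicate noise acts at the peptide × replicate level (all transitions
  of a peptide rise and fall together, as an injection does) and the
  per-peptide log-multipliers are standardised so the planted log-scale
  scatter equals ``noise_cv`` exactly — the generator plants the
  dispersion rather than drawing it, which makes %CV recovery a sharp
  test at 3 replicates;
* unstable peptides receive a deterministic monotone decay across
  replicates (what autosampler degradation over days looks like) of
  magnitude ``unstable_extra_cv`` on top of the ordinary noise, so a
  planted-unstable peptide fails a 20% CV screen for every seed.

Presets re-create the composition of the two worked examples: a
chronic-pain panel (87 candidate proteins of which 2 are undetected and,
of the 85 detected, 67 carry at least 2 peptides with at least 5 clean
transitions) and an Alzheimer's-disease panel (180 candidates, 170
detected, 96 with at least 2 peptides, with a synthetic reference list
sharing 50 peptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ConfigurationError, REPORT_COLUMNS, StandardPeptide

_RESIDUES = list("ACDEFGHLMNPQSTVWY")  # K/R kept terminal for a tryptic look


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults emulate a small
    triplicate DIA screen of a pooled sample."""

    seed: int = 0
    n_proteins: int = 20
    peptides_per_protein: Tuple[int, int] = (2, 5)
    transitions_per_peptide: Tuple[int, int] = (5, 8)
    n_replicates: int = 3
    #: lognormal peptide base abundance: (mean of log, sd of log)
    abundance: Tuple[float, float] = (13.0, 1.0)
    #: fractional multiplicative noise per replicate (0.10 = 10% CV)
    noise_cv: float = 0.10
    frac_interfered_transitions: float = 0.05
    interference_shift_min: float = 0.5
    frac_unstable_peptides: float = 0.05
    unstable_extra_cv: float = 0.6
    #: linear iRT -> RT model: (slope min/iRT, intercept min, jitter SD min)
    rt_model: Tuple[float, float, float] = (0.5, 5.0, 0.02)
    #: geometric decay ratio of transition intensity over rank
    intensity_decay: float = 0.7
    preset: Optional[str] = None

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_proteins and n_replicates must be >= 1")
        for name in ("peptides_per_protein", "transitions_per_peptide"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"{name} must be a range with 1 <= lo <= hi")
        for name in ("frac_interfered_transitions", "frac_unstable_peptides"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_cv < 0 or self.unstable_extra_cv < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if not (0 < self.intensity_decay <= 1):
            raise ConfigurationError("intensity_decay must lie in (0, 1]")
        if self.preset not in (None, "pain_panel", "ad_panel"):
            raise ConfigurationError(f"unknown preset {self.preset!r}")


@dataclass
class _PeptidePlan:
    protein_id: str
    n_transitions: int
    unstable: bool
    n_interfered: int


@dataclass
class SyntheticReport:
    """Generated report plus planted ground truth."""

    report: pd.DataFrame
    truth_transitions: pd.DataFrame
    truth_peptides: pd.DataFrame
    truth_proteins: pd.DataFrame
    #: reference peptide list for overlap comparison (ad_panel preset only)
    reference: Optional[pd.DataFrame] = None


def _random_sequences(rng: np.random.Generator, n: int) -> List[str]:
    seqs: List[str] = []
    seen = set()
    while len(seqs) < n:
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(_RESIDUES, size=length))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return seqs


def _replicate_multipliers(
    rng: np.random.Generator, n_replicates: int, noise_cv: float, unstable: bool, extra_cv: float
) -> np.ndarray:
    mult = np.ones(n_replicates)
    if noise_cv > 0 and n_replicates > 1:
        z = rng.standard_normal(n_replicates)
        sd = z.std(ddof=1)
        if sd > 0:
            z = (z - z.mean()) / sd
            mult = np.exp(noise_cv * z)
    if unstable and extra_cv > 0 and n_replicates > 1:
        drift = np.linspace(1.0, -1.0, n_replicates)
        mult = mult * np.exp(extra_cv * drift)
    return mult


def _build_report(
    plans: Sequence[_PeptidePlan], config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    slope, intercept, jitter_sd = config.rt_model
    n_rep = config.n_replicates
    replicate_ids = [f"rep{r + 1}" for r in range(n_rep)]
    sequences = _random_sequences(rng, len(plans))

    report_rows = []
    truth_transition_rows = []
    truth_peptide_rows = []
    for plan, seq in zip(plans, sequences):
        m = plan.n_transitions
        charge = int(rng.choice([2, 3]))
        precursor_mz = float(np.round(rng.uniform(400.0, 1000.0), 4))
        irt = float(rng.uniform(0.0, 100.0))
        base = float(rng.lognormal(config.abundance[0], config.abundance[1]))
        rt_true = slope * irt + intercept

        rel = config.intensity_decay ** np.arange(m)
        product_mz = np.round(rng.uniform(200.0, 1250.0, size=m), 4)
        ions = [f"y{m + 2 - k}+" for k in range(m)]

        k_interfered = min(plan.n_interfered, (m - 1) // 2)
        interfered_idx = (
            rng.choice(m, size=k_interfered, replace=False) if k_interfered else np.array([], dtype=int)
        )
        shifts = np.zeros(m)
        for j, idx in enumerate(sorted(interfered_idx)):
            shifts[idx] = config.interference_shift_min * (1 if j % 2 == 0 else -1)

        mult = _replicate_multipliers(
            rng, n_rep, config.noise_cv, plan.unstable, config.unstable_extra_cv
        )
        jitter = (
            rng.normal(0.0, jitter_sd, size=(m, n_rep)) if jitter_sd > 0 else np.zeros((m, n_rep))
        )
        for t in range(m):
            for r in range(n_rep):
                report_rows.append(
                    (
                        plan.protein_id,
                        seq,
                        charge,
                        precursor_mz,
                        ions[t],
                        float(product_mz[t]),
                        replicate_ids[r],
                        float(base * rel[t] * mult[r]),
                        float(max(0.0, rt_true + shifts[t] + jitter[t, r])),
                    )
                )
            truth_transition_rows.append(
                (plan.protein_id, seq, charge, ions[t], bool(shifts[t] != 0.0))
            )
        truth_peptide_rows.append(
            (plan.protein_id, seq, charge, plan.unstable, irt, base, m, k_interfered)
        )

    report = pd.DataFrame(report_rows, columns=list(REPORT_COLUMNS))
    truth_transitions = pd.DataFrame(
        truth_transition_rows,
        columns=["protein_id", "peptide_seq", "precursor_charge", "product_ion", "interfered"],
    )
    truth_peptides = pd.DataFrame(
        truth_peptide_rows,
        columns=[
            "protein_id",
            "peptide_seq",
            "precursor_charge",
            "unstable",
            "irt",
            "base_abundance",
            "n_transitions",
            "n_interfered",
        ],
    )
    return report, truth_transitions, truth_peptides


def generate_report(config: SyntheticConfig) -> SyntheticReport:
    """Generate a synthetic transition report with ground-truth tables.

    Deterministic given ``config.seed``.  With a preset configured the
    protein composition is planted (see module docstring); otherwise
    peptide counts, transition counts, unstable peptides and interfered
    transitions are drawn from the configured ranges and fractions.
    """
    config.validate()
    if config.preset == "pain_panel":
        return _generate_pain_panel(config)
    if config.preset == "ad_panel":
        return _generate_ad_panel(config)
    rng = np.random.default_rng(config.seed)

    plans: List[_PeptidePlan] = []
    protein_rows = []
    for i in range(config.n_proteins):
        protein_id = f"PROT{i + 1:04d}"
        protein_rows.append((protein_id, True, None, None))
        n_pep = int(rng.integers(config.peptides_per_protein[0], config.peptides_per_protein[1] + 1))
        for _ in range(n_pep):
            m = int(
                rng.integers(
                    config.transitions_per_peptide[0], config.transitions_per_peptide[1] + 1
                )
            )
            plans.append(
                _PeptidePlan(
                    protein_id=protein_id,
                    n_transitions=m,
                    unstable=bool(rng.random() < config.frac_unstable_peptides),
                    n_interfered=int(rng.binomial(m, config.frac_interfered_transitions)),
                )
            )
    report, truth_transitions, truth_peptides = _build_report(plans, config, rng)
    truth_proteins = pd.DataFrame(
        protein_rows, columns=["protein_id", "detected", "expected_pass", "fail_reason"]
    )
    return SyntheticReport(report, truth_transitions, truth_peptides, truth_proteins)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: dropped-protein log reasons, kept in sync with srmbuilder.selection
_REASON_FEW_PEPTIDES = "too_few_qualifying_peptides"
_REASON_FEW_CLEAN = "too_few_clean_transitions"
_REASON_CV = "cv_above_threshold"


def preset_pain_panel(seed: int) -> SyntheticConfig:
    """Configuration for the chronic-pain panel worked example.

    Plants 87 candidate proteins: 2 undetected; of the 85 detected,
    exactly 67 pass a screen requiring at least 2 peptides with at least
    5 clean co-eluting transitions and %CV ≤ 20, and 18 fail with
    deterministically cycled failure modes (too few qualifying peptides /
    too few clean transitions / CV above threshold).  Low measurement
    noise and a large planted apex shift make the composition
    seed-invariant.
    """
    return SyntheticConfig(
        seed=seed,
        n_proteins=87,
        transitions_per_peptide=(6, 6),
        noise_cv=0.03,
        frac_interfered_transitions=0.0,
        interference_shift_min=1.0,
        frac_unstable_peptides=0.0,
        unstable_extra_cv=0.6,
        rt_model=(0.5, 5.0, 0.01),
        preset="pain_panel",
    )


def preset_ad_panel(seed: int) -> SyntheticConfig:
    """Configuration for the Alzheimer's-disease panel worked example.

    Plants 180 candidate proteins: 10 undetected, 74 detected with a
    single peptide, and 96 detected with 2 well-behaved peptides each
    (the selection unit); the companion reference list shares both
    peptides for 25 of those proteins (50 shared peptides) and disjoint
    peptides elsewhere.
    """
    return SyntheticConfig(
        seed=seed,
        n_proteins=180,
        transitions_per_peptide=(5, 5),
        noise_cv=0.03,
        frac_interfered_transitions=0.0,
        interference_shift_min=1.0,
        frac_unstable_peptides=0.0,
        rt_model=(0.5, 5.0, 0.01),
        preset="ad_panel",
    )


def _generate_pain_panel(config: SyntheticConfig) -> SyntheticReport:
    rng = np.random.default_rng(config.seed)
    fail_modes = [_REASON_FEW_PEPTIDES, _REASON_FEW_CLEAN, _REASON_CV]
    plans: List[_PeptidePlan] = []
    protein_rows = []
    m = config.transitions_per_peptide[1]
    for i in range(config.n_proteins):
        protein_id = f"PAIN{i + 1:03d}"
        if i < 2:
            protein_rows.append((protein_id, False, False, "not_detected"))
            continue
        if i < 2 + 67:
            protein_rows.append((protein_id, True, True, None))
            for _ in range(3):
                plans.append(_PeptidePlan(protein_id, m, unstable=False, n_interfered=0))
            continue
        mode = fail_modes[(i - 69) % 3]
        protein_rows.append((protein_id, True, False, mode))
        if mode == _REASON_FEW_PEPTIDES:
            plans.append(_PeptidePlan(protein_id, m, unstable=False, n_interfered=0))
        elif mode == _REASON_FEW_CLEAN:
            for _ in range(2):
                plans.append(_PeptidePlan(protein_id, m, unstable=False, n_interfered=2))
        else:
            for _ in range(2):
                plans.append(_PeptidePlan(protein_id, m, unstable=True, n_interfered=0))
    report, truth_transitions, truth_peptides = _build_report(plans, config, rng)
    truth_proteins = pd.DataFrame(
        protein_rows, columns=["protein_id", "detected", "expected_pass", "fail_reason"]
    )
    return SyntheticReport(report, truth_transitions, truth_peptides, truth_proteins)


def _generate_ad_panel(config: SyntheticConfig) -> SyntheticReport:
    rng = np.random.default_rng(config.seed)
    plans: List[_PeptidePlan] = []
    protein_rows = []
    m = config.transitions_per_peptide[1]
    n_two_pep = 96
    n_one_pep = 74
    for i in range(config.n_proteins):
        protein_id = f"ADP{i + 1:03d}"
        if i >= n_two_pep + n_one_pep:
            protein_rows.append((protein_id, False, False, "not_detected"))
            continue
        n_pep = 2 if i < n_two_pep else 1
        passes = n_pep >= 2
        protein_rows.append(
            (protein_id, True, passes, None if passes else _REASON_FEW_PEPTIDES)
        )
        for _ in range(n_pep):
            plans.append(_PeptidePlan(protein_id, m, unstable=False, n_interfered=0))
    report, truth_transitions, truth_peptides = _build_report(plans, config, rng)
    truth_proteins = pd.DataFrame(
        protein_rows, columns=["protein_id", "detected", "expected_pass", "fail_reason"]
    )

    # Reference list: identical peptide pairs for the first 25 two-peptide
    # proteins (50 shared peptides), disjoint peptides for the rest.
    reference_rows = []
    decoy_seqs = iter(_random_sequences(rng, 2 * (n_two_pep - 25)))
    two_pep_proteins = [f"ADP{i + 1:03d}" for i in range(n_two_pep)]
    by_protein = truth_peptides.groupby("protein_id")
    for j, protein_id in enumerate(two_pep_proteins):
        group = by_protein.get_group(protein_id)
        if j < 25:
            for row in group.itertuples(index=False):
                reference_rows.append((protein_id, row.peptide_seq, row.precursor_charge))
        else:
            for _ in range(2):
                reference_rows.append((protein_id, next(decoy_seqs), 2))
    reference = pd.DataFrame(
        reference_rows, columns=["protein_id", "peptide_seq", "precursor_charge"]
    )
    return SyntheticReport(
        report, truth_transitions, truth_peptides, truth_proteins, reference=reference
    )


def generate_standards(
    seed: int,
    rt_model: Tuple[float, float, float] = (0.5, 5.0, 0.0),
    n_standards: int = 13,
    transitions_per_standard: int = 3,
) -> List[StandardPeptide]:
    """Synthetic retention-time standards (a PRTC-like mixture).

    iRT values are spread evenly over [0, 100]; measured RT follows the
    given linear model with optional jitter (the model's third element).
    """
    rng = np.random.default_rng(seed)
    slope, intercept, jitter_sd = rt_model
    irts = np.linspace(0.0, 100.0, n_standards)
    standards = []
    for i, irt in enumerate(irts):
        measured = slope * irt + intercept
        if jitter_sd > 0:
            measured += rng.normal(0.0, jitter_sd)
        standards.append(
            StandardPeptide(
                name=f"STD{i + 1:02d}",
                irt=float(irt),
                measured_rt=float(measured),
                precursor_mz=float(np.round(rng.uniform(450.0, 900.0), 4)),
                precursor_charge=2,
                transitions=[
                    (f"y{k + 3}+", float(np.round(rng.uniform(300.0, 1100.0), 4)))
                    for k in range(transitions_per_standard)
                ],
            )
        )
    return standards
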