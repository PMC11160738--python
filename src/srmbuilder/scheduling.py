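"""Retention-time calibration, scheduled windows, collision energies and
capacity-limited method partitioning.

iRT standards spiked into every sample give each peptide a dimensionless
retention index transferable between LC setups.  A linear fit of
measured RT on iRT over the standards calibrates a given setup; targets
are scheduled in a fixed-width window centred on their predicted RT.
Because a triple quadrupole can only cycle through a bounded number of
transitions at once, targets are partitioned greedily (first-fit in RT
order) into as many methods as needed to keep the peak number of
concurrent transitions within the configured capacity.  Standards are
monitored across the whole gradient in every method, so they count
against capacity everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import (
    CalibrationError,
    CapacityError,
    ConfigurationError,
    ScheduleConfig,
    StandardPeptide,
    StateError,
)
from .selection import AssayTarget


@dataclass
class RTCalibration:
    """Linear iRT → RT mapping fitted from standards by ordinary least squares."""

    slope: float  # minutes per iRT unit
    intercept: float  # minutes
    rmse: float  # minutes
    n_standards: int
    slope_stderr: float = float("nan")

    def predict(self, irt: float) -> float:
        return self.slope * irt + self.intercept

    def invert(self, rt: float) -> float:
        return (rt - self.intercept) / self.slope


@dataclass
class ScheduledMethod:
    """One capacity-feasible instrument method."""

    index: int
    targets: List[AssayTarget]
    standards: List[StandardPeptide]
    peak_concurrency: int
    peak_time: float
    gradient_length_min: float

    @property
    def n_transitions(self) -> int:
        return sum(len(t.transitions) for t in self.targets) + sum(
            len(s.transitions) for s in self.standards
        )


def calibrate_rt(standards: Sequence[StandardPeptide]) -> RTCalibration:
    """Fit measured RT on iRT over standards with measured retention times.

    Raises :class:`CalibrationError` with fewer than two usable standards
    or when all iRT values coincide.
    """
    usable = [s for s in standards if s.measured_rt is not None]
    if len(usable) < 2:
        raise CalibrationError(
            f"need at least 2 standards with measured RT, got {len(usable)}"
        )
    irt = np.array([s.irt for s in usable], dtype=float)
    rt = np.array([s.measured_rt for s in usable], dtype=float)
    if np.ptp(irt) == 0:
        raise CalibrationError("all standards share one iRT value; cannot fit a line")
    fit = stats.linregress(irt, rt)
    residuals = rt - (fit.slope * irt + fit.intercept)
    return RTCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        n_standards=len(usable),
        slope_stderr=float(fit.stderr),
    )


def assign_windows(
    targets: Sequence[AssayTarget],
    calibration: RTCalibration,
    schedule: ScheduleConfig,
    gradient_length: Optional[float] = None,
) -> List[str]:
    """Assign predicted RT and a scheduling window to every target (in place).

    The window is ``predicted_rt ± window_min/2`` intersected with
    ``[0, gradient_length]``; targets predicted outside the gradient are
    clipped to a reduced-width window and reported in the returned
    warning list.
    """
    if gradient_length is None:
        gradient_length = schedule.gradient_length_min
    warnings: List[str] = []
    half = schedule.window_min / 2.0
    for target in targets:
        if target.irt is None:
            raise StateError(
                f"target {target.peptide_seq}/{target.precursor_charge} has no iRT value"
            )
        predicted = calibration.predict(target.irt)
        if predicted < 0 or predicted > gradient_length:
            warnings.append(
                f"{target.peptide_seq}/{target.precursor_charge}: predicted RT "
                f"{predicted:.2f} min outside gradient [0, {gradient_length:g}]"
            )
        target.predicted_rt = predicted
        clip = lambda x: min(gradient_length, max(0.0, x))  # noqa: E731
        target.window = (clip(predicted - half), clip(predicted + half))
    return warnings


def collision_energy(
    precursor_mz: float,
    charge: int,
    coefficients: Mapping[int, Tuple[float, float]],
) -> float:
    """Charge-dependent linear collision energy, rounded to 0.1 eV.

    ``CE = slope(charge) × precursor_mz + intercept(charge)``; charges
    without coefficients fall back to the highest charge defined.
    """
    if not coefficients:
        raise ConfigurationError("no collision-energy coefficients configured")
    if charge in coefficients:
        slope, intercept = coefficients[charge]
    else:
        fallback = max(coefficients)
        slope, intercept = coefficients[fallback]
    return round(slope * precursor_mz + intercept, 1)


def assign_collision_energies(
    targets: Sequence[AssayTarget], schedule: ScheduleConfig
) -> None:
    for target in targets:
        target.collision_energy = collision_energy(
            target.precursor_mz, target.precursor_charge, schedule.ce_coefficients
        )


def _standard_transition_count(standards: Sequence[StandardPeptide]) -> int:
    return sum(len(s.transitions) for s in standards)


def concurrency_profile(
    targets: Sequence[AssayTarget],
    standards: Sequence[StandardPeptide] = (),
) -> Tuple[int, float]:
    """Peak number of simultaneously monitored transitions, and when it first occurs.

    Sweep over sorted window endpoints; each target contributes its
    transition count over the half-open interval ``[start, end)`` (so
    abutting windows do not double-count), and standards contribute their
    transitions over the entire run.  Returns ``(peak, earliest time)``.
    """
    baseline = _standard_transition_count(standards)
    events: List[Tuple[float, int, int]] = []
    for target in targets:
        if target.window is None:
            raise StateError(
                f"target {target.peptide_seq}/{target.precursor_charge} has no window"
            )
        start, end = target.window
        weight = len(target.transitions)
        # order key 0 = closings first at equal times (half-open intervals)
        events.append((end, 0, -weight))
        events.append((start, 1, weight))
    events.sort()
    peak, peak_time, current = baseline, 0.0, baseline
    for time, _, delta in events:
        current += delta
        if current > peak:
            peak, peak_time = current, time
    return peak, peak_time


def partition_methods(
    targets: Sequence[AssayTarget],
    standards: Sequence[StandardPeptide],
    schedule: ScheduleConfig,
    gradient_length: Optional[float] = None,
) -> List[ScheduledMethod]:
    """Partition targets into capacity-feasible methods (greedy first-fit).

    Targets are placed in order of predicted RT (ties broken by peptide
    sequence) into the first method whose peak concurrency — including
    the full standards set, monitored over the whole gradient — stays
    within ``max_concurrent_transitions``; a new method is opened when
    none fits.  Greedy, not provably minimal.
    """
    if gradient_length is None:
        gradient_length = schedule.gradient_length_min
    capacity = schedule.max_concurrent_transitions
    baseline = _standard_transition_count(standards)
    if baseline >= capacity:
        raise CapacityError(
            f"standards alone use {baseline} of {capacity} concurrent transitions"
        )
    for target in targets:
        if target.predicted_rt is None or target.window is None:
            raise StateError(
                f"target {target.peptide_seq}/{target.precursor_charge} is not scheduled yet"
            )
        if len(target.transitions) + baseline > capacity:
            raise CapacityError(
                f"target {target.peptide_seq}/{target.precursor_charge} needs "
                f"{len(target.transitions)} transitions plus {baseline} standard "
                f"transitions, exceeding capacity {capacity}"
            )

    ordered = sorted(targets, key=lambda t: (t.predicted_rt, t.peptide_seq))
    bins: List[List[AssayTarget]] = []
    for target in ordered:
        placed = False
        for bin_targets in bins:
            peak, _ = concurrency_profile(bin_targets + [target], standards)
            if peak <= capacity:
                bin_targets.append(target)
                placed = True
                break
        if not placed:
            bins.append([target])

    methods = []
    for i, bin_targets in enumerate(bins, start=1):
        peak, peak_time = concurrency_profile(bin_targets, standards)
        methods.append(
            ScheduledMethod(
                index=i,
                targets=bin_targets,
                standards=list(standards),
                peak_concurrency=peak,
                peak_time=peak_time,
                gradient_length_min=gradient_length,
            )
        )
    return methods
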