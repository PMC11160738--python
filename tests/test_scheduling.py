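import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import srmbuilder as sb
from srmbuilder.model import CapacityError, ConfigurationError, ScheduleConfig
from srmbuilder.scheduling import (
    assign_windows,
    calibrate_rt,
    collision_energy,
    concurrency_profile,
    partition_methods,
)
from srmbuilder.selection import AssayTarget, AssayTransition

from conftest import grid_concurrency


def _standard(irt, rt):
    return sb.StandardPeptide(name=f"S{irt}", irt=irt, measured_rt=rt)


def _target(seq="AK", n_transitions=5, irt=None, window=None, rt=None, mz=500.0, charge=2):
    return AssayTarget(
        protein_id="P1",
        peptide_seq=seq,
        precursor_charge=charge,
        precursor_mz=mz,
        transitions=[
            AssayTransition(f"y{j + 3}+", 600.0 + j, j + 1) for j in range(n_transitions)
        ],
        irt=irt,
        predicted_rt=rt,
        window=window,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def test_two_point_calibration():
    cal = calibrate_rt([_standard(0.0, 10.0), _standard(100.0, 60.0)])
    assert cal.slope == pytest.approx(0.5)
    assert cal.intercept == pytest.approx(10.0)
    assert cal.rmse == pytest.approx(0.0, abs=1e-12)
    assert cal.invert(cal.predict(42.0)) == pytest.approx(42.0)


def test_perfectly_linear_standards_zero_rmse():
    standards = [_standard(irt, 0.4 * irt + 3.0) for irt in np.linspace(0, 100, 13)]
    cal = calibrate_rt(standards)
    assert cal.rmse == pytest.approx(0.0, abs=1e-10)
    assert cal.n_standards == 13


def test_calibration_errors():
    with pytest.raises(sb.CalibrationError):
        calibrate_rt([_standard(0.0, 10.0)])
    with pytest.raises(sb.CalibrationError):
        calibrate_rt([_standard(5.0, 10.0), _standard(5.0, 12.0)])


def test_slope_recovery_from_noisy_standards():
    """OLS recovers the planted slope: MC mean within 3 SE over 100 seeds."""
    a, b = 0.45, 3.0
    slopes, stderrs = [], []
    for seed in range(100):
        standards = sb.generate_standards(seed, rt_model=(a, b, 0.1))
        cal = calibrate_rt(standards)
        slopes.append(cal.slope)
        stderrs.append(cal.slope_stderr)
    mc_se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
    assert abs(np.mean(slopes) - a) < 3 * mc_se
    covered = np.mean([abs(s - a) < 3 * se for s, se in zip(slopes, stderrs)])
    assert covered >= 0.95


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def test_window_centred_on_predicted_rt():
    cal = calibrate_rt([_standard(0.0, 0.0), _standard(100.0, 100.0)])
    target = _target(irt=30.0)
    warnings = assign_windows([target], cal, ScheduleConfig(window_min=5.0), 60.0)
    assert warnings == []
    assert target.window == pytest.approx((27.5, 32.5))


def test_window_clipped_at_gradient_start():
    cal = calibrate_rt([_standard(0.0, 0.0), _standard(100.0, 100.0)])
    target = _target(irt=1.0)
    assign_windows([target], cal, ScheduleConfig(window_min=5.0), 60.0)
    assert target.window == pytest.approx((0.0, 3.5))


def test_out_of_gradient_target_warned_and_clipped():
    cal = calibrate_rt([_standard(0.0, 0.0), _standard(100.0, 100.0)])
    target = _target(irt=62.0)
    warnings = assign_windows([target], cal, ScheduleConfig(window_min=5.0), 60.0)
    assert len(warnings) == 1
    assert target.window == pytest.approx((59.5, 60.0))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(irt=st.floats(-20, 120), window=st.floats(0.5, 10), gradient=st.floats(10, 120))
def test_window_width_never_exceeds_configured(irt, window, gradient):
    cal = calibrate_rt([_standard(0.0, 0.0), _standard(100.0, 100.0)])
    target = _target(irt=irt)
    assign_windows([target], cal, ScheduleConfig(window_min=window), gradient)
    lo, hi = target.window
    assert 0 <= lo <= hi <= gradient
    assert hi - lo <= window + 1e-12


# ---------------------------------------------------------------------------
# Collision energy
# ---------------------------------------------------------------------------


def test_collision_energy_linear():
    assert collision_energy(500.0, 2, {2: (0.03, 2.9)}) == pytest.approx(17.9)


def test_collision_energy_fallback_to_highest_charge():
    coeffs = {2: (0.03, 2.905), 3: (0.038, 2.281)}
    assert collision_energy(700.0, 4, coeffs) == collision_energy(700.0, 3, coeffs)


def test_collision_energy_requires_coefficients():
    with pytest.raises(ConfigurationError):
        collision_energy(500.0, 2, {})


def test_collision_energy_monotone_in_mz():
    ces = [collision_energy(mz, 2, {2: (0.03, 2.9)}) for mz in range(400, 1000, 50)]
    assert ces == sorted(ces)
    assert len(set(ces)) == len(ces)


# ---------------------------------------------------------------------------
# Concurrency
# ---------------------------------------------------------------------------


def test_disjoint_windows_peak_is_single_target():
    targets = [
        _target(seq="AK", window=(10.0, 15.0)),
        _target(seq="BK", window=(20.0, 25.0)),
    ]
    peak, _ = concurrency_profile(targets)
    assert peak == 5


def test_identical_windows_with_standards():
    standards = sb.generate_standards(0)  # 13 standards x 3 transitions = 39
    targets = [
        _target(seq="AK", window=(10.0, 15.0)),
        _target(seq="BK", window=(10.0, 15.0)),
    ]
    peak, when = concurrency_profile(targets, standards)
    assert peak == 49
    assert when == pytest.approx(10.0)


def test_abutting_windows_do_not_double_count():
    targets = [
        _target(seq="AK", window=(10.0, 15.0)),
        _target(seq="BK", window=(15.0, 20.0)),
    ]
    peak, _ = concurrency_profile(targets)
    assert peak == 5


def _random_schedule(rng, n_targets=None):
    n = n_targets or int(rng.integers(2, 40))
    targets = []
    for i in range(n):
        start = float(rng.uniform(0, 55))
        width = float(rng.uniform(0.5, 8.0))
        targets.append(
            _target(
                seq=f"PEP{i:03d}K",
                n_transitions=int(rng.integers(1, 8)),
                rt=start + width / 2,
                window=(start, min(60.0, start + width)),
            )
        )
    return targets


def test_sweep_matches_dense_grid_oracle():
    rng = np.random.default_rng(99)
    for _ in range(50):
        targets = _random_schedule(rng)
        standards = sb.generate_standards(0) if rng.random() < 0.5 else []
        peak, _ = concurrency_profile(targets, standards)
        assert peak == grid_concurrency(targets, standards)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


def test_everything_fits_single_method():
    standards = sb.generate_standards(0)
    targets = _random_schedule(np.random.default_rng(1), n_targets=10)
    methods = partition_methods(
        targets, standards, ScheduleConfig(max_concurrent_transitions=200)
    )
    assert len(methods) == 1
    assert methods[0].peak_concurrency <= 200


@pytest.mark.parametrize("n_targets,capacity", [(12, 50), (7, 60), (20, 48)])
def test_identical_window_closed_form(n_targets, capacity):
    standards = sb.generate_standards(0)  # 39 transitions
    s, t = 39, 5
    targets = [
        _target(seq=f"PEP{i:03d}K", n_transitions=t, rt=30.0, window=(27.5, 32.5))
        for i in range(n_targets)
    ]
    methods = partition_methods(
        targets, standards, ScheduleConfig(max_concurrent_transitions=capacity)
    )
    assert len(methods) == math.ceil(n_targets / ((capacity - s) // t))


def test_partition_feasible_and_conserving():
    rng = np.random.default_rng(5)
    standards = sb.generate_standards(0)
    for _ in range(20):
        targets = _random_schedule(rng)
        capacity = int(rng.integers(46, 120))  # >= 39 standards + largest target (7)
        methods = partition_methods(
            targets, standards, ScheduleConfig(max_concurrent_transitions=capacity)
        )
        all_pairs = []
        for method in methods:
            assert grid_concurrency(method.targets, standards) <= capacity
            assert [s.name for s in method.standards] == [s.name for s in standards]
            for target in method.targets:
                for transition in target.transitions:
                    all_pairs.append((target.peptide_seq, transition.product_ion))
        expected = sorted(
            (t.peptide_seq, tr.product_ion) for t in targets for tr in t.transitions
        )
        assert sorted(all_pairs) == expected  # each transition exactly once


def test_method_count_non_increasing_with_capacity():
    rng = np.random.default_rng(17)
    standards = sb.generate_standards(0)
    targets = _random_schedule(rng, n_targets=30)
    counts = [
        len(
            partition_methods(
                targets, standards, ScheduleConfig(max_concurrent_transitions=cap)
            )
        )
        for cap in (48, 60, 80, 120, 200)
    ]
    assert counts == sorted(counts, reverse=True)


def test_oversized_target_raises_capacity_error():
    standards = sb.generate_standards(0)
    target = _target(seq="BIGPEPK", n_transitions=7, rt=30.0, window=(27.5, 32.5))
    with pytest.raises(CapacityError, match="BIGPEPK"):
        partition_methods([target], standards, ScheduleConfig(max_concurrent_transitions=45))
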