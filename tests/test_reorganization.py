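"""Reorganization: tumble/run semantics, quiescence, and the WMRSE metric."""

import numpy as np
import pytest

from pctsim import (
    ReorgConfig,
    ReorgState,
    TargetSet,
    build_three_level_conflict,
    reorg_step,
    reorg_update,
    wmrse,
)
from pctsim.control_core import SimulationTrace


def _trace_from_errors(e: np.ndarray) -> SimulationTrace:
    n, u = e.shape
    zeros = np.zeros_like(e)
    return SimulationTrace(
        dt=0.016,
        unit_ids=[f"u{i}" for i in range(u)],
        env_ids=["env0"],
        p=zeros, r=e.copy(), e=e.copy(), qo=zeros,
        qi=np.zeros((n, 1)), d=np.zeros((n, 1)),
    )


def naive_wmrse(e: np.ndarray, window: int, stride: int = 1) -> np.ndarray:
    """Independent double-loop evaluation of the windowed error metric."""
    n, u = e.shape
    out = []
    for start in range(0, n - window + 1, stride):
        acc = 0.0
        count = 0
        for t in range(start, start + window):
            for k in range(u):
                acc += e[t, k] ** 2
                count += 1
        out.append(np.sqrt(acc / count))
    return np.array(out)


class TestWMRSE:
    def test_all_zero_errors(self):
        assert np.all(wmrse(np.zeros((30, 4))) == 0.0)

    def test_constant_two_unit_case(self):
        """Two units with constant errors 3 and 4 give sqrt((9+16)/2) everywhere."""
        e = np.column_stack([np.full(25, 3.0), np.full(25, 4.0)])
        series = wmrse(_trace_from_errors(e), window=10)
        assert series.shape == (16,)
        assert np.allclose(series, np.sqrt(12.5), atol=1e-12)

    def test_matches_naive_oracle_on_random_traces(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 60))
            u = int(rng.integers(1, 5))
            e = rng.normal(0, 3, (n, u))
            w = int(rng.integers(1, n + 1))
            assert np.allclose(wmrse(e, window=w), naive_wmrse(e, w), atol=1e-12)

    def test_strided_variant_matches_naive(self, rng):
        e = rng.normal(0, 1, (40, 3))
        assert np.allclose(wmrse(e, window=10, stride=10), naive_wmrse(e, 10, 10),
                           atol=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            wmrse(np.zeros((5, 1)), window=6)
        with pytest.raises(ValueError):
            wmrse(np.zeros((5, 1)), window=0)


class TestReorgUpdate:
    def config(self, **kw):
        base = dict(window=10, step_coefficient=0.1, target_set=TargetSet.MID_LEVEL_WEIGHTS,
                    error_tolerance=0.0, rng_seed=3)
        base.update(kw)
        return ReorgConfig(**base)

    def test_quiescent_at_zero_error(self):
        config = self.config()
        state = ReorgState.initial(2, config)
        values = np.array([0.5, -0.5])
        new_values, new_state, event = reorg_update(values, 0.0, state, config)
        assert np.array_equal(new_values, values)
        assert not event["tumbled"]
        assert event["step_size"] == 0.0

    def test_frozen_while_error_below_tolerance(self):
        config = self.config(error_tolerance=1.0)
        state = ReorgState.initial(2, config)
        values = np.array([0.3, 0.7])
        for err in (0.9, 0.5, 0.99, 0.2):
            values_new, state, event = reorg_update(values, err, state, config)
            assert np.array_equal(values_new, values)

    def test_tumble_step_norm_proportional_to_current_error(self):
        """On a tumble the perturbation norm is step_coefficient times the
        current windowed error, exactly."""
        config = self.config(step_coefficient=0.1)
        state = ReorgState(previous_window_error=1.0, direction=np.zeros(2),
                           step_size=0.0, rng=np.random.default_rng(0))
        values = np.zeros(2)
        new_values, new_state, event = reorg_update(values, 2.0, state, config)
        assert event["tumbled"]
        assert np.linalg.norm(new_values - values) == pytest.approx(0.2, abs=1e-12)
        assert new_state.step_size == pytest.approx(0.1 * 2.0, abs=1e-15)

    def test_run_keeps_direction_and_step(self):
        """Improving error continues the previous move unchanged (a 'run')."""
        config = self.config()
        state = ReorgState(previous_window_error=0.0, direction=np.zeros(2),
                           step_size=0.0, rng=np.random.default_rng(5))
        values = np.zeros(2)
        values, state, ev1 = reorg_update(values, 4.0, state, config)  # tumble
        assert ev1["tumbled"]
        direction = state.direction.copy()
        step = state.step_size
        values2, state2, ev2 = reorg_update(values, 3.0, state, config)  # improved
        assert not ev2["tumbled"]
        assert np.array_equal(state2.direction, direction)
        assert state2.step_size == step
        assert np.allclose(values2 - values, step * direction, atol=1e-15)

    def test_clipping_flagged(self):
        config = self.config(step_coefficient=10.0, clip_bound=1.0)
        state = ReorgState(previous_window_error=0.0, direction=np.zeros(2),
                           step_size=0.0, rng=np.random.default_rng(1))
        new_values, _, event = reorg_update(np.zeros(2), 5.0, state, config)
        assert event["clipped"]
        assert np.all(np.abs(new_values) <= 1.0)

    def test_deterministic_sequences(self):
        def run_sequence(seed):
            config = self.config(rng_seed=seed)
            state = ReorgState.initial(2, config)
            values = np.zeros(2)
            errors = [3.0, 4.0, 2.0, 5.0, 1.0]
            out = []
            for err in errors:
                values, state, _ = reorg_update(values, err, state, config)
                out.append(values.copy())
            return np.array(out)

        assert np.array_equal(run_sequence(9), run_sequence(9))
        assert not np.array_equal(run_sequence(9), run_sequence(10))


class TestReorgStepTargets:
    def test_none_target_is_noop(self):
        arch = build_three_level_conflict(rng_seed=1)
        config = ReorgConfig(target_set=TargetSet.NONE, rng_seed=0)
        state = ReorgState.initial(1, config)
        new_arch, new_state = reorg_step(arch, config, state, 10.0)
        assert new_arch is arch
        assert new_state.previous_window_error == 10.0

    @pytest.mark.parametrize(
        "target, changed_keys",
        [
            (TargetSet.TOP_LEVEL_WEIGHTS, "top_to_mid"),
            (TargetSet.MID_LEVEL_WEIGHTS, "mid_to_low"),
        ],
    )
    def test_only_targeted_weights_change(self, target, changed_keys):
        arch = build_three_level_conflict(rng_seed=2)
        config = ReorgConfig(target_set=target, step_coefficient=0.1, rng_seed=4)
        state = ReorgState.initial(2, config)
        new_arch, _ = reorg_step(arch, config, state, 5.0)
        changed = set(getattr(arch, changed_keys))
        for key, old in arch.network.reference_weights.items():
            new = new_arch.network.reference_weights[key]
            if key in changed:
                assert new != old
            else:
                assert new == old

    def test_gain_target_changes_only_mid_gains(self):
        arch = build_three_level_conflict(rng_seed=3)
        config = ReorgConfig(target_set=TargetSet.MID_LEVEL_GAINS, rng_seed=4)
        state = ReorgState.initial(2, config)
        new_arch, _ = reorg_step(arch, config, state, 5.0)
        assert new_arch.network.reference_weights == arch.network.reference_weights
        old_gains = [arch.network.params(k).output_gain for k in (arch.MID_A, arch.MID_B)]
        new_gains = [new_arch.network.params(k).output_gain
                     for k in (new_arch.MID_A, new_arch.MID_B)]
        assert old_gains != new_gains
        assert new_arch.network.params(arch.TOP).output_gain == \
            arch.network.params(arch.TOP).output_gain


def test_reorg_config_validation():
    with pytest.raises(ValueError):
        ReorgConfig(window=0)
    with pytest.raises(ValueError):
        ReorgConfig(step_coefficient=0.0)
    with pytest.raises(ValueError):
        ReorgConfig(error_tolerance=-1.0)
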