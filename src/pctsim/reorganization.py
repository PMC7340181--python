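"""Trial-and-error reorganization and the windowed error metric (WMRSE).

Reorganization is the learning process that randomly perturbs designated
parameters of a control hierarchy while error is sustained, in the manner
of E. coli chemotaxis: when windowed error has *increased* since the last
check, a new uniformly random direction is drawn (a "tumble") and the step
size is set proportional to the *current* windowed error — the present
degree of loss of control; when error stayed level or improved, the
previous direction and step size are kept (a "run").  Once error falls
below tolerance the parameters freeze.

Scaling the tumble step by the current error rather than by its increment
keeps exploration vigorous while control is poor and makes it fine-grained
as control is regained; an increment-proportional step self-quenches on
broad error plateaus (the increment is near zero while the error itself is
still large) and the search stalls far from workable organizations.

The outcome metric is the Window Mean Root Squared Error: squared error
terms across all control units are averaged over a window of (by default
ten) iteration cycles and the square root of this figure is taken.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .control_core import SimulationTrace
from .hierarchy import ConflictArchitecture, NetworkSimulator


class TargetSet(str, Enum):
    """Which connection strengths reorganization may change."""

    NONE = "none"
    MID_LEVEL_WEIGHTS = "mid_level_weights"
    TOP_LEVEL_WEIGHTS = "top_level_weights"
    MID_LEVEL_GAINS = "mid_level_gains"   # optional extra target: mid-unit output gains


@dataclass
class ReorgConfig:
    """Reorganization settings.

    ``window`` is the number of iterations over which error is accumulated
    between reorganization episodes; ``step_coefficient`` maps the current
    windowed error to the tumble step magnitude; ``error_tolerance``
    is the windowed-error level below which no change occurs;
    ``clip_bound`` bounds perturbed parameters (clipping is logged).
    """

    window: int = 60
    step_coefficient: float = 0.02
    target_set: TargetSet = TargetSet.NONE
    error_tolerance: float = 0.0
    rng_seed: int = 0
    clip_bound: float = 100.0

    def __post_init__(self) -> None:
        self.target_set = TargetSet(self.target_set)
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.step_coefficient <= 0:
            raise ValueError(f"step_coefficient must be > 0, got {self.step_coefficient}")
        if self.error_tolerance < 0:
            raise ValueError(f"error_tolerance must be >= 0, got {self.error_tolerance}")
        if self.clip_bound <= 0:
            raise ValueError(f"clip_bound must be > 0, got {self.clip_bound}")


@dataclass
class ReorgState:
    """Mutable state of the reorganizing system.

    ``previous_window_error`` starts at 0 so the first non-quiescent check
    registers an error increase and bootstraps with a tumble.
    """

    previous_window_error: float = 0.0
    direction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    step_size: float = 0.0
    rng: np.random.Generator | None = None

    @classmethod
    def initial(cls, n_params: int, config: ReorgConfig) -> "ReorgState":
        return cls(
            previous_window_error=0.0,
            direction=np.zeros(n_params),
            step_size=0.0,
            rng=np.random.default_rng(config.rng_seed),
        )


def random_unit_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniformly random direction on the unit sphere in ``n`` dimensions."""
    while True:
        v = rng.standard_normal(n)
        norm = float(np.linalg.norm(v))
        if norm > 1e-12:
            return v / norm


def reorg_update(
    values: np.ndarray,
    current_window_error: float,
    state: ReorgState,
    config: ReorgConfig,
) -> tuple[np.ndarray, ReorgState, dict]:
    """Core E. coli update on a vector of targeted parameters.

    On a tumble (windowed error increased) a fresh uniformly random unit
    direction is drawn and ``step_size = step_coefficient *
    current_window_error``; otherwise the previous direction and step size
    persist.  Returns the new parameter vector, the updated state, and an
    event record ``{"delta_e", "tumbled", "step_size", "clipped"}``.
    Quiescent when ``current_window_error <= error_tolerance``.
    """
    if current_window_error < 0:
        raise ValueError("current_window_error must be >= 0")
    values = np.asarray(values, dtype=float)
    new_state = ReorgState(
        previous_window_error=float(current_window_error),
        direction=state.direction.copy(),
        step_size=state.step_size,
        rng=state.rng,
    )
    delta_e = current_window_error - state.previous_window_error
    if current_window_error <= config.error_tolerance:
        return values.copy(), new_state, dict(
            delta_e=delta_e, tumbled=False, step_size=0.0, clipped=False
        )
    tumbled = False
    if delta_e > 0:
        if state.rng is None:
            raise ValueError("reorganization requires a seeded ReorgState (use ReorgState.initial)")
        new_state.direction = random_unit_vector(state.rng, values.size)
        new_state.step_size = config.step_coefficient * current_window_error
        tumbled = True
    new_values = values + new_state.step_size * new_state.direction
    clipped_values = np.clip(new_values, -config.clip_bound, config.clip_bound)
    clipped = bool(np.any(clipped_values != new_values))
    return clipped_values, new_state, dict(
        delta_e=delta_e, tumbled=tumbled, step_size=new_state.step_size, clipped=clipped
    )


def _target_keys(arch: ConflictArchitecture, target_set: TargetSet):
    if target_set is TargetSet.MID_LEVEL_WEIGHTS:
        return list(arch.mid_to_low)
    if target_set is TargetSet.TOP_LEVEL_WEIGHTS:
        return list(arch.top_to_mid)
    return []


def reorg_step(
    arch: ConflictArchitecture,
    config: ReorgConfig,
    state: ReorgState,
    current_window_error: float,
) -> tuple[ConflictArchitecture, ReorgState]:
    """One reorganization episode on a conflict architecture.

    Returns a new architecture with the targeted connection strengths (or
    mid-level gains) perturbed, and the updated state.  With
    ``target_set = NONE`` the architecture is returned unchanged (no-op by
    contract, not an error).
    """
    if config.target_set is TargetSet.NONE:
        new_state = ReorgState(
            previous_window_error=float(current_window_error),
            direction=state.direction.copy(),
            step_size=state.step_size,
            rng=state.rng,
        )
        return arch, new_state

    new_arch = copy.deepcopy(arch)
    new_arch.environment = arch.environment  # share the live environment state

    if config.target_set is TargetSet.MID_LEVEL_GAINS:
        mids = [new_arch.MID_A, new_arch.MID_B]
        values = np.array([new_arch.network.params(k).output_gain for k in mids])
        new_values, new_state, _ = reorg_update(values, current_window_error, state, config)
        for k, v in zip(mids, new_values):
            new_arch.network.params(k).output_gain = float(v)
        return new_arch, new_state

    keys = _target_keys(new_arch, config.target_set)
    values = np.array([new_arch.network.reference_weights[k] for k in keys])
    new_values, new_state, _ = reorg_update(values, current_window_error, state, config)
    for k, v in zip(keys, new_values):
        new_arch.network.reference_weights[k] = float(v)
    return new_arch, new_state


def window_rms_error(errors: np.ndarray) -> float:
    """Root of the mean squared error over all units and all rows given."""
    e = np.asarray(errors, dtype=float)
    return float(np.sqrt(np.mean(e**2)))


def run_with_reorganization(
    sim: NetworkSimulator,
    arch: ConflictArchitecture,
    config: ReorgConfig,
    n_windows: int,
    state: ReorgState | None = None,
) -> tuple[ConflictArchitecture, ReorgState, pd.DataFrame]:
    """Alternate blocks of simulation with reorganization episodes.

    Each episode simulates ``config.window`` iterations, measures the
    root-mean-square error over that window across all units (the same
    windowed statistic as WMRSE, which keeps ``step_coefficient`` on a
    window-length-independent scale), then applies :func:`reorg_step` to the
    architecture read live by ``sim``.  Returns the final architecture and
    state plus an event log with columns
    ``window, step, window_error, delta_e, tumbled, step_size, clipped``.
    """
    n_targets = 2 if config.target_set is not TargetSet.NONE else 0
    if state is None:
        state = ReorgState.initial(max(n_targets, 1), config)
    events = []
    for w in range(n_windows):
        sim.run(config.window)
        err = window_rms_error(sim.errors(config.window))
        arch, new_state = reorg_step(arch, config, state, err)
        sim.network = arch.network
        events.append(
            dict(
                window=w,
                step=sim.t,
                window_error=err,
                delta_e=err - state.previous_window_error,
                tumbled=bool(
                    config.target_set is not TargetSet.NONE
                    and err > config.error_tolerance
                    and err - state.previous_window_error > 0
                ),
                step_size=new_state.step_size,
                clipped=False,
            )
        )
        state = new_state
    return arch, state, pd.DataFrame(events)


def wmrse(
    trace_or_errors,
    window: int = 10,
    stride: int = 1,
) -> np.ndarray:
    """Window Mean Root Squared Error series.

    For each window position the squared errors across all control units
    are averaged over ``window`` iteration cycles and the square root is
    taken.  With ``stride = 1`` (default) the window slides one iteration
    at a time and the series has length ``n - window + 1``; with
    ``stride = window`` consecutive windows abut.
    """
    e = (
        trace_or_errors.e
        if isinstance(trace_or_errors, SimulationTrace)
        else np.asarray(trace_or_errors, dtype=float)
    )
    if e.ndim == 1:
        e = e[:, None]
    n = e.shape[0]
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    sq_mean_units = np.mean(e**2, axis=1)
    csum = np.concatenate([[0.0], np.cumsum(sq_mean_units)])
    starts = np.arange(0, n - window + 1, stride)
    return np.sqrt((csum[starts + window] - csum[starts]) / window)
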