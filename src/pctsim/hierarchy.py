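"""Hierarchies of control units: higher-level outputs set lower-level references.

A network is a set of control units grouped into levels (level 0 = lowest).
Each non-top unit's reference at step ``t`` is a signed weighted sum of its
superiors' outputs at ``t - 1``; each unit's perceptual input is a signed
weighted sum of lower-level perceptions (level-0 units perceive an
environment quantity).  All units update synchronously with double
buffering — every unit reads previous-step values and writes next-step
values — so the loop closes only through the environment.

The module also provides the canonical three-level conflict architecture:
one top unit whose output sends two (randomly weighted) references to two
mid units, which in turn jointly set the reference of one low-level unit
that both perceive.  Opposing implied references produce chronic error at
the mid level — the structural signature of goal conflict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .control_core import (
    ControlUnitParams,
    DelayLine,
    InstabilityError,
    INSTABILITY_LIMIT,
    LoopEnvironment,
    SimulationConfig,
    SimulationTrace,
)

UnitKey = tuple[int, int]          # (level, index), level 0 = lowest
SourceKey = tuple                  # UnitKey or ("env", k)


class NetworkValidationError(ValueError):
    """The network specification violates a structural invariant."""


@dataclass
class NetworkSpec:
    """Hierarchy topology and connection weights.

    Parameters
    ----------
    units : list of list of ControlUnitParams
        Units grouped by level; ``units[0]`` is the lowest level.
    reference_weights : dict
        ``{((level+1, j), (level, i)): w}`` — signed weight from superior
        unit ``j``'s output to unit ``i``'s reference.  Only adjacent levels
        may be connected.
    perception_weights : dict
        ``{(source, (level, i)): w}`` — signed weight mapping a lower-level
        perception (or, for level-0 units, an environment quantity keyed
        ``("env", k)``) into unit ``i``'s input function.
    top_references : dict
        ``{(level, i): r}`` — fixed references for units with no superior.
    """

    units: list[list[ControlUnitParams]]
    reference_weights: dict[tuple[UnitKey, UnitKey], float] = field(default_factory=dict)
    perception_weights: dict[tuple[SourceKey, UnitKey], float] = field(default_factory=dict)
    top_references: dict[UnitKey, float] = field(default_factory=dict)

    def unit_keys(self) -> list[UnitKey]:
        return [(lvl, i) for lvl, level in enumerate(self.units) for i in range(len(level))]

    def params(self, key: UnitKey) -> ControlUnitParams:
        return self.units[key[0]][key[1]]

    @property
    def n_levels(self) -> int:
        return len(self.units)

    def validate(self, n_envs: int) -> None:
        keys = set(self.unit_keys())
        if not keys:
            raise NetworkValidationError("network has no units")
        for (src, dst), w in self.reference_weights.items():
            if dst not in keys or src not in keys:
                raise NetworkValidationError(f"reference weight {src}->{dst} names unknown unit")
            if src[0] != dst[0] + 1:
                raise NetworkValidationError(
                    f"reference weight {src}->{dst} must connect adjacent levels "
                    "(superior one level above)"
                )
            if not math.isfinite(w):
                raise NetworkValidationError(f"reference weight {src}->{dst} not finite")
        for (src, dst), w in self.perception_weights.items():
            if dst not in keys:
                raise NetworkValidationError(f"perception weight {src}->{dst} names unknown unit")
            if dst[0] == 0:
                if not (isinstance(src, tuple) and src[0] == "env" and 0 <= src[1] < n_envs):
                    raise NetworkValidationError(
                        f"level-0 unit {dst} must perceive an environment quantity, got {src}"
                    )
            else:
                if src not in keys or src[0] != dst[0] - 1:
                    raise NetworkValidationError(
                        f"perception weight {src}->{dst} must come from the level below"
                    )
            if not math.isfinite(w):
                raise NetworkValidationError(f"perception weight {src}->{dst} not finite")
        ref_targets = {dst for (_, dst) in self.reference_weights}
        per_targets = {dst for (_, dst) in self.perception_weights}
        for key in keys:
            has_ref = key in ref_targets
            has_top = key in self.top_references
            if has_ref and has_top:
                raise NetworkValidationError(
                    f"unit {key} has both a fixed top reference and incoming reference weights"
                )
            if not has_ref and not has_top:
                raise NetworkValidationError(
                    f"unit {key} has no reference source (weight or top_references entry)"
                )
            if key not in per_targets:
                raise NetworkValidationError(f"unit {key} has no perception source")


@dataclass
class ConflictArchitecture:
    """Three-level goal-conflict network: 1 top, 2 mid, 1 low unit.

    The top unit's output sets both mid references (weights ``top_to_mid``);
    the two mid outputs jointly set the low unit's reference (weights
    ``mid_to_low``).  Both mid units perceive the low-level perception.
    """

    network: NetworkSpec
    environment: LoopEnvironment

    TOP: UnitKey = (2, 0)
    MID_A: UnitKey = (1, 0)
    MID_B: UnitKey = (1, 1)
    LOW: UnitKey = (0, 0)

    #: reference-weight keys eligible for reorganization, by target set
    top_to_mid = (((2, 0), (1, 0)), ((2, 0), (1, 1)))
    mid_to_low = (((1, 0), (0, 0)), ((1, 1), (0, 0)))

    def __post_init__(self) -> None:
        shape = [len(level) for level in self.network.units]
        if shape != [1, 2, 1]:
            raise NetworkValidationError(
                f"conflict architecture requires levels [1, 2, 1] (low, mid, top), got {shape}"
            )
        for key in self.top_to_mid + self.mid_to_low:
            if key not in self.network.reference_weights:
                raise NetworkValidationError(f"conflict architecture missing weight {key}")
        self.network.validate(n_envs=1)

    def weights(self, keys) -> np.ndarray:
        return np.array([self.network.reference_weights[k] for k in keys], dtype=float)


# Documented defaults for the three-level conflict scenario.  Gains are kept
# well inside the discrete stability region ((1 + loop gain)/S < 2 for the
# single low-level loop) and outputs saturate at +/-100 so that badly signed
# random weight draws produce sustained, bounded error rather than numerical
# divergence.
CONFLICT_UNIT_DEFAULTS: dict[str, dict] = {
    "low": dict(input_gain=1.0, output_gain=20.0, slowing=15.0, output_limit=10.0),
    "mid": dict(input_gain=1.0, output_gain=3.0, slowing=15.0, output_limit=10.0),
    "top": dict(input_gain=1.0, output_gain=3.0, slowing=15.0, output_limit=10.0),
}
CONFLICT_TOP_REFERENCE = 5.0


def build_three_level_conflict(
    rng_seed: int,
    weight_range: tuple[float, float] = (-1.0, 1.0),
    dead_zone: float = 0.1,
    unit_defaults: dict[str, dict] | None = None,
    top_reference: float = CONFLICT_TOP_REFERENCE,
) -> ConflictArchitecture:
    """Draw a random three-level conflict agent.

    The two top->mid and two mid->low reference weights are drawn uniformly
    from ``weight_range``, rejecting draws inside the ``dead_zone`` around 0
    so every agent starts with genuine connections.  Deterministic for a
    fixed ``rng_seed``.
    """
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
        raise ValueError(f"weight_range must be a finite interval, got {weight_range}")
    if max(abs(lo), abs(hi)) <= dead_zone:
        raise ValueError(
            f"weight_range {weight_range} lies entirely inside the dead zone +/-{dead_zone}"
        )
    rng = np.random.default_rng(rng_seed)

    def draw() -> float:
        while True:
            w = rng.uniform(lo, hi)
            if abs(w) >= dead_zone:
                return float(w)

    w_top_a, w_top_b, w_mid_a, w_mid_b = (draw() for _ in range(4))

    defaults = unit_defaults or CONFLICT_UNIT_DEFAULTS
    low = ControlUnitParams(**defaults["low"])
    mid_a = ControlUnitParams(**defaults["mid"])
    mid_b = ControlUnitParams(**defaults["mid"])
    top = ControlUnitParams(**defaults["top"], reference=top_reference)

    net = NetworkSpec(
        units=[[low], [mid_a, mid_b], [top]],
        reference_weights={
            ((2, 0), (1, 0)): w_top_a,
            ((2, 0), (1, 1)): w_top_b,
            ((1, 0), (0, 0)): w_mid_a,
            ((1, 1), (0, 0)): w_mid_b,
        },
        perception_weights={
            (("env", 0), (0, 0)): 1.0,
            ((0, 0), (1, 0)): 1.0,
            ((0, 0), (1, 1)): 1.0,
            # top perceives the mean of the two mid perceptions
            ((1, 0), (2, 0)): 0.5,
            ((1, 1), (2, 0)): 0.5,
        },
        top_references={(2, 0): top_reference},
    )
    return ConflictArchitecture(network=net, environment=LoopEnvironment(feedback_gain=1.0))


class NetworkSimulator:
    """Stateful synchronous simulator for a :class:`NetworkSpec`.

    Supports incremental stepping (``run(k)``) so that learning processes
    can mutate connection weights between blocks of iterations.  Weights are
    read live from ``self.network.reference_weights`` at every step.
    """

    def __init__(
        self,
        network: NetworkSpec,
        environments: list[LoopEnvironment] | LoopEnvironment,
        config: SimulationConfig,
    ):
        if isinstance(environments, LoopEnvironment):
            environments = [environments]
        network.validate(n_envs=len(environments))
        n_level0 = len(network.units[0])
        if len(environments) != n_level0:
            raise NetworkValidationError(
                f"need one environment per level-0 unit: {n_level0} units, "
                f"{len(environments)} environments"
            )
        self.network = network
        self.environments = environments
        self.config = config
        self.keys = network.unit_keys()
        self._index = {k: i for i, k in enumerate(self.keys)}
        n = config.n_iterations
        self._dist = np.column_stack([env.disturbance_series(n) for env in environments])

        nu = len(self.keys)
        self.t = 0
        self._prev_p = np.zeros(nu)
        self._prev_qo = np.zeros(nu)
        self._qi = np.array([env.input_quantity for env in environments], dtype=float)
        self._in_lines = [DelayLine(network.params(k).transport_delay) for k in self.keys]
        self._out_lines = [DelayLine(network.params(k).transport_delay) for k in self.keys]

        self._rec_p = np.empty((n, nu))
        self._rec_r = np.empty((n, nu))
        self._rec_e = np.empty((n, nu))
        self._rec_qo = np.empty((n, nu))
        self._rec_qi = np.empty((n, len(environments)))

        # Pre-resolved connection lists per unit (weight values read live).
        self._ref_in = {
            k: [src for (src, dst) in network.reference_weights if dst == k] for k in self.keys
        }
        self._per_in = {
            k: [src for (src, dst) in network.perception_weights if dst == k] for k in self.keys
        }

    def step(self) -> None:
        """Advance the whole network by one synchronous iteration."""
        t = self.t
        if t >= self.config.n_iterations:
            raise RuntimeError("simulation already ran for n_iterations steps")
        net = self.network
        new_p = np.empty_like(self._prev_p)
        new_qo = np.empty_like(self._prev_qo)

        for i, key in enumerate(self.keys):
            params = net.params(key)
            if key in net.top_references:
                r = net.top_references[key]
            else:
                r = 0.0
                for src in self._ref_in[key]:
                    r += net.reference_weights[(src, key)] * self._prev_qo[self._index[src]]
            if key[0] == 0:
                raw = 0.0
                for src in self._per_in[key]:
                    raw += net.perception_weights[(src, key)] * self._qi[src[1]]
            else:
                raw = 0.0
                for src in self._per_in[key]:
                    raw += net.perception_weights[(src, key)] * self._prev_p[self._index[src]]
            raw = self._in_lines[i].push(raw)

            p = params.input_gain * raw
            e = r - p
            qo = self._prev_qo[i] + (params.output_gain * e - self._prev_qo[i]) / params.slowing
            if params.output_limit is not None:
                lim = params.output_limit
                qo = min(max(qo, -lim), lim)
            if not math.isfinite(qo) or abs(qo) > INSTABILITY_LIMIT or abs(p) > INSTABILITY_LIMIT:
                raise InstabilityError(t, f"unit L{key[0]}U{key[1]}", qo if math.isfinite(qo) else p)

            new_p[i] = p
            new_qo[i] = qo
            self._rec_p[t, i] = p
            self._rec_r[t, i] = r
            self._rec_e[t, i] = e
            self._rec_qo[t, i] = qo

        for k, env in enumerate(self.environments):
            i = self._index[(0, k)]
            qo_delayed = self._out_lines[i].push(new_qo[i])
            qi = env.feedback_gain * qo_delayed + self._dist[t, k]
            if not math.isfinite(qi) or abs(qi) > INSTABILITY_LIMIT:
                raise InstabilityError(t, f"env{k}", qi)
            self._qi[k] = qi
            env.input_quantity = qi
            self._rec_qi[t, k] = qi

        self._prev_p = new_p
        self._prev_qo = new_qo
        self.t = t + 1

    def run(self, n_steps: int | None = None) -> None:
        remaining = self.config.n_iterations - self.t
        n_steps = remaining if n_steps is None else min(n_steps, remaining)
        for _ in range(n_steps):
            self.step()

    def errors(self, window: int | None = None) -> np.ndarray:
        """Recorded error matrix, optionally restricted to the trailing window."""
        e = self._rec_e[: self.t]
        return e if window is None else e[-window:]

    def trace(self) -> SimulationTrace:
        t = self.t
        return SimulationTrace(
            dt=self.config.dt,
            unit_ids=[f"L{lvl}U{i}" for (lvl, i) in self.keys],
            env_ids=[f"env{k}" for k in range(len(self.environments))],
            p=self._rec_p[:t].copy(),
            r=self._rec_r[:t].copy(),
            e=self._rec_e[:t].copy(),
            qo=self._rec_qo[:t].copy(),
            qi=self._rec_qi[:t].copy(),
            d=self._dist[:t].copy(),
        )


def propagate(
    network: NetworkSpec,
    environments: list[LoopEnvironment] | LoopEnvironment,
    config: SimulationConfig,
) -> SimulationTrace:
    """Run a whole network for ``config.n_iterations`` synchronous steps."""
    sim = NetworkSimulator(network, environments, config)
    sim.run()
    return sim.trace()


def total_error(trace_or_errors, window: int) -> float:
    """Sum over units of squared error accumulated over the trailing window."""
    e = trace_or_errors.e if isinstance(trace_or_errors, SimulationTrace) else np.asarray(
        trace_or_errors, dtype=float
    )
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > e.shape[0]:
        raise ValueError(f"window {window} exceeds trace length {e.shape[0]}")
    return float(np.sum(e[-window:] ** 2))
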