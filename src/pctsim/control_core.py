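"""Single negative-feedback control unit closed through an environment.

The basic building block of a perceptual control model is a unit that keeps
a perceived quantity ``p`` near an internally held reference ``r`` by acting
on the environment.  The discrete update used throughout this package is

    p   <- Ki * Qi(t - d)                  (input function)
    e   <- r - p                           (comparator)
    Qo  <- Qo + (Ko * e - Qo) / S          (amplified, leaky-integrated output)
    Qi  <- Kf * Qo(t - d) + D(t)           (environmental feedback + disturbance)

where ``Ki`` is the input gain, ``Ko`` the output gain, ``S >= 1`` the
slowing time-constant of the leaky integrator (in iterations), ``d`` the
transport delay (whole iterations, applied to both the perceptual and the
output path), ``Kf`` the environmental feedback gain and ``D`` the
disturbance.  One call to :func:`step_unit` advances exactly one iteration;
an iteration nominally spans 16 ms of simulated time (``dt = 0.016``),
mirroring the refresh rate of the synchronous multi-unit simulations built
on top of this module.

With constant ``r`` and ``D`` the loop has the closed-form fixed point

    e* = (r - Ki * D) / (1 + Ki * Kf * Ko)

exposed by :func:`analytic_steady_state` and used as the simulation oracle
in the test-suite.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Any signal whose magnitude exceeds this is treated as loop divergence.
INSTABILITY_LIMIT = 1e9

#: Nominal wall-clock duration of one iteration, in seconds.
DEFAULT_DT = 0.016


class InstabilityError(RuntimeError):
    """A control loop diverged (signal magnitude exceeded ``INSTABILITY_LIMIT``)."""

    def __init__(self, step: int, entity: str, value: float):
        self.step = step
        self.entity = entity
        self.value = value
        super().__init__(
            f"control loop diverged at step {step}: |{entity}| = {value:.3g} "
            f"exceeds instability limit {INSTABILITY_LIMIT:.0e}"
        )


class DegenerateLoopError(ValueError):
    """The loop gain makes the steady-state denominator vanish."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass
class ControlUnitParams:
    """Parameters of one control loop.

    Parameters
    ----------
    input_gain : float
        ``Ki``, scaling from the environmental input quantity to the
        perceptual signal.
    output_gain : float
        ``Ko``, error amplification inside the leaky-integrator output
        function.
    slowing : float
        ``S >= 1``, leaky-integrator time constant in iterations.  ``S = 1``
        gives a purely proportional output ``Qo = Ko * e``.
    transport_delay : int
        Non-negative whole-iteration delay applied to the perceptual and
        output paths.
    reference : float
        ``r``, the goal state for the perception.  In hierarchies this is
        overwritten each step by superior units' outputs.
    output_limit : float, optional
        Physiological saturation bound on ``|Qo|``.  ``None`` (default)
        leaves the output unbounded.
    """

    input_gain: float = 1.0
    output_gain: float = 1.0
    slowing: float = 1.0
    transport_delay: int = 0
    reference: float = 0.0
    output_limit: float | None = None

    def __post_init__(self) -> None:
        for name in ("input_gain", "output_gain", "slowing", "reference"):
            _require_finite(name, float(getattr(self, name)))
        if self.slowing < 1:
            raise ValueError(f"slowing must be >= 1, got {self.slowing}")
        if int(self.transport_delay) != self.transport_delay or self.transport_delay < 0:
            raise ValueError(
                f"transport_delay must be a non-negative integer, got {self.transport_delay}"
            )
        self.transport_delay = int(self.transport_delay)
        if self.output_limit is not None and self.output_limit <= 0:
            raise ValueError("output_limit must be positive or None")


@dataclass
class LoopEnvironment:
    """Environmental side of a loop: feedback path, disturbance, input quantity.

    ``disturbance`` may be a scalar (held constant) or a 1-D array defining
    the disturbance at every simulated step.
    """

    feedback_gain: float = 1.0
    disturbance: float | np.ndarray = 0.0
    input_quantity: float = 0.0

    def disturbance_series(self, n_iterations: int) -> np.ndarray:
        """Disturbance value for each of ``n_iterations`` steps."""
        d = np.asarray(self.disturbance, dtype=float)
        if d.ndim == 0:
            return np.full(n_iterations, float(d))
        if d.ndim != 1 or d.shape[0] < n_iterations:
            raise ValueError(
                f"disturbance must be scalar or a 1-D series of length >= "
                f"{n_iterations}, got shape {d.shape}"
            )
        if not np.all(np.isfinite(d[:n_iterations])):
            raise ValueError("disturbance contains non-finite values")
        return d[:n_iterations]


@dataclass
class UnitState:
    """Instantaneous signals of a unit: perception, error, output quantity."""

    perception: float = 0.0
    error: float = 0.0
    output_quantity: float = 0.0


@dataclass
class SimulationConfig:
    """Bookkeeping for a simulation run.

    ``dt`` is metadata only — the dynamics are expressed per iteration — and
    defaults to 0.016 s, the synchronous refresh interval of the combined
    simulations.
    """

    dt: float = DEFAULT_DT
    n_iterations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")


class DelayLine:
    """Whole-iteration transport delay buffer, initialized to zeros.

    ``push(x)`` returns the value from ``length`` iterations ago (``x``
    itself for a zero-length line).
    """

    def __init__(self, length: int):
        if length < 0:
            raise ValueError("delay length must be >= 0")
        self.length = int(length)
        self._buf: deque[float] = deque([0.0] * self.length, maxlen=self.length or 1)

    def push(self, value: float) -> float:
        if self.length == 0:
            return value
        delayed = self._buf[0]
        self._buf.append(value)
        return delayed


@dataclass
class SimulationTrace:
    """Time-indexed record of every unit's signals plus environment quantities.

    Arrays ``p, r, e, qo`` have shape ``(n_steps, n_units)``; ``qi, d`` have
    shape ``(n_steps, n_envs)``.  The comparator identity ``e = r - p``
    holds exactly at every recorded step.
    """

    dt: float
    unit_ids: list[str]
    env_ids: list[str]
    p: np.ndarray
    r: np.ndarray
    e: np.ndarray
    qo: np.ndarray
    qi: np.ndarray
    d: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.p.shape[0]

    @property
    def n_units(self) -> int:
        return self.p.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: step, time_s, entity_id, signal, value."""
        frames = []
        steps = np.arange(self.n_steps)
        for signal, arr, ids in (
            ("p", self.p, self.unit_ids),
            ("r", self.r, self.unit_ids),
            ("e", self.e, self.unit_ids),
            ("Qo", self.qo, self.unit_ids),
            ("Qi", self.qi, self.env_ids),
            ("D", self.d, self.env_ids),
        ):
            for k, entity in enumerate(ids):
                frames.append(
                    pd.DataFrame(
                        {
                            "step": steps,
                            "time_s": steps * self.dt,
                            "entity_id": entity,
                            "signal": signal,
                            "value": arr[:, k],
                        }
                    )
                )
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["step", "entity_id", "signal"], kind="stable").reset_index(
            drop=True
        )


def step_unit(
    params: ControlUnitParams,
    env: LoopEnvironment,
    state: UnitState,
    disturbance: float = 0.0,
    input_delay: DelayLine | None = None,
    output_delay: DelayLine | None = None,
    step: int = 0,
) -> UnitState:
    """Advance one loop by exactly one iteration.

    The environment's ``input_quantity`` is updated in place after the unit
    fires (perceive -> compare -> output -> environment).  Delay lines are
    only needed when ``params.transport_delay > 0``; callers that step a
    loop repeatedly should create them once and pass them in.
    """
    d = params.transport_delay
    if d > 0 and (input_delay is None or output_delay is None):
        raise ValueError("transport_delay > 0 requires explicit delay lines")
    qi_delayed = input_delay.push(env.input_quantity) if input_delay else env.input_quantity

    p = params.input_gain * qi_delayed
    e = params.reference - p
    qo = state.output_quantity + (params.output_gain * e - state.output_quantity) / params.slowing
    if params.output_limit is not None:
        lim = params.output_limit
        qo = min(max(qo, -lim), lim)

    qo_delayed = output_delay.push(qo) if output_delay else qo
    qi = env.feedback_gain * qo_delayed + disturbance

    for name, value in (("p", p), ("Qo", qo), ("Qi", qi)):
        if not math.isfinite(value) or abs(value) > INSTABILITY_LIMIT:
            raise InstabilityError(step, name, value)

    env.input_quantity = qi
    return UnitState(perception=p, error=e, output_quantity=qo)


def run_single_loop(
    params: ControlUnitParams,
    env: LoopEnvironment,
    config: SimulationConfig,
) -> SimulationTrace:
    """Simulate one closed loop for ``config.n_iterations`` steps.

    Returns a :class:`SimulationTrace` whose per-step comparator identity
    ``e = r - p`` holds exactly.  Raises :class:`InstabilityError` (with the
    offending step index) if any signal exceeds ``INSTABILITY_LIMIT``.
    """
    n = config.n_iterations
    disturbance = env.disturbance_series(n)
    in_line = DelayLine(params.transport_delay)
    out_line = DelayLine(params.transport_delay)

    p = np.empty((n, 1))
    r = np.empty((n, 1))
    e = np.empty((n, 1))
    qo = np.empty((n, 1))
    qi = np.empty((n, 1))

    state = UnitState()
    for t in range(n):
        state = step_unit(
            params,
            env,
            state,
            disturbance=float(disturbance[t]),
            input_delay=in_line,
            output_delay=out_line,
            step=t,
        )
        p[t, 0] = state.perception
        r[t, 0] = params.reference
        e[t, 0] = state.error
        qo[t, 0] = state.output_quantity
        qi[t, 0] = env.input_quantity

    return SimulationTrace(
        dt=config.dt,
        unit_ids=["unit0"],
        env_ids=["env0"],
        p=p,
        r=r,
        e=e,
        qo=qo,
        qi=qi,
        d=disturbance.reshape(-1, 1).copy(),
    )


def analytic_steady_state(
    params: ControlUnitParams,
    env: LoopEnvironment,
    constant_disturbance: float = 0.0,
) -> tuple[float, float, float]:
    """Closed-form fixed point ``(p*, e*, Qo*)`` of the loop update.

    Valid for constant reference and disturbance and an unsaturated output
    (``output_limit`` not binding).  Transport delay and slowing shift the
    transient but not the fixed point.

    Raises
    ------
    DegenerateLoopError
        If ``1 + Ki * Kf * Ko`` is numerically zero, i.e. the loop gain
        exactly cancels the comparator and no unique fixed point exists.
    """
    loop_gain = params.input_gain * env.feedback_gain * params.output_gain
    denom = 1.0 + loop_gain
    if abs(denom) < 1e-9:
        raise DegenerateLoopError(
            f"loop gain Ki*Kf*Ko = {loop_gain:.6g} makes 1 + Ki*Kf*Ko ~ 0; "
            "the loop has no unique steady state"
        )
    e_star = (params.reference - params.input_gain * constant_disturbance) / denom
    p_star = params.reference - e_star
    qo_star = params.output_gain * e_star
    if params.output_limit is not None and abs(qo_star) > params.output_limit:
        raise ValueError(
            "analytic steady state requires an unsaturated output; "
            f"|Qo*| = {abs(qo_star):.3g} exceeds output_limit = {params.output_limit}"
        )
    return p_star, e_star, qo_star
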