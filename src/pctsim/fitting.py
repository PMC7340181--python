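"""Fitting control models to tracking trajectories.

Manual pursuit-tracking data (a target trajectory and the cursor movements
made to follow it) can be modelled either by a single position-control loop
or by a two-level hierarchy in which a proximity-control system sets
reference values for a velocity-control system.  This module generates
synthetic tracking datasets from known ground-truth parameters and
recovers parameters by derivative-free optimization, statsmodels-style:
build a :class:`TrackingModel` from a :class:`TrackingDataset`, call
``fit()``, and get a :class:`FitResult` with estimates, the objective
(RMSE between simulated and observed cursor), the model--data correlation
and a ``summary()`` table.

Discrete model equations (one iteration per sample, delays in whole
iterations applied to the perceived tracking error):

one-level position control::

    e  = target(t - d) - cursor(t - d)
    Qo <- Qo + (g * e - Qo) / s
    cursor <- cursor + kv * Qo                (kv = 0.1, fixed)

two-level velocity control::

    e1  = target(t - d) - cursor(t - d)
    Qo1 <- Qo1 + (g1 * e1 - Qo1) / s1         (reference velocity)
    e2  = Qo1 - v
    Qo2 <- Qo2 + (g2 * e2 - Qo2) / s2
    v   <- v + kv * Qo2
    cursor <- cursor + v
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .control_core import InstabilityError

#: Fixed velocity scale from output quantity to cursor movement per iteration.
KV = 0.1

#: Cursor magnitudes beyond this are treated as a diverged (unstable) model.
_DIVERGE_LIMIT = 1e6

ONE_LEVEL = "one_level_position"
TWO_LEVEL = "two_level_velocity"

#: Optimization bounds per parameter, by model kind.
PARAM_BOUNDS = {
    ONE_LEVEL: {"gain": (0.05, 30.0), "slowing": (1.0, 30.0)},
    TWO_LEVEL: {
        "gain1": (0.05, 10.0), "slowing1": (1.0, 20.0),
        "gain2": (0.05, 20.0), "slowing2": (1.0, 20.0),
    },
}
DELAY_GRID = (0, 1, 2, 3)

#: Default ground truths for synthetic data (gain(s), slowing(s), delay).
TRUE_ONE_LEVEL = {"gain": 3.0, "slowing": 4.0, "delay": 2}
TRUE_TWO_LEVEL = {"gain1": 0.3, "slowing1": 3.0, "gain2": 8.0, "slowing2": 2.0, "delay": 2}


def simulate_tracker(
    target: np.ndarray,
    params: dict,
    model_kind: str = ONE_LEVEL,
    raise_on_divergence: bool = True,
) -> np.ndarray:
    """Simulate the cursor a control model produces while tracking ``target``."""
    target = np.asarray(target, dtype=float)
    n = target.size
    cursor_out = np.empty(n)
    d = int(params.get("delay", 0))
    hist = [0.0] * d
    cursor = 0.0
    if model_kind == ONE_LEVEL:
        g, s = params["gain"], params["slowing"]
        qo = 0.0
        for t in range(n):
            raw = target[t] - cursor
            if d:
                hist.append(raw)
                e = hist.pop(0)
            else:
                e = raw
            qo += (g * e - qo) / s
            cursor += KV * qo
            if abs(cursor) > _DIVERGE_LIMIT:
                if raise_on_divergence:
                    raise InstabilityError(t, "cursor", cursor)
                cursor_out[t:] = math.copysign(_DIVERGE_LIMIT, cursor)
                return cursor_out
            cursor_out[t] = cursor
        return cursor_out
    if model_kind == TWO_LEVEL:
        g1, s1 = params["gain1"], params["slowing1"]
        g2, s2 = params["gain2"], params["slowing2"]
        qo1 = qo2 = v = 0.0
        for t in range(n):
            raw = target[t] - cursor
            if d:
                hist.append(raw)
                e1 = hist.pop(0)
            else:
                e1 = raw
            qo1 += (g1 * e1 - qo1) / s1
            e2 = qo1 - v
            qo2 += (g2 * e2 - qo2) / s2
            v += KV * qo2
            cursor += v
            if abs(cursor) > _DIVERGE_LIMIT:
                if raise_on_divergence:
                    raise InstabilityError(t, "cursor", cursor)
                cursor_out[t:] = math.copysign(_DIVERGE_LIMIT, cursor)
                return cursor_out
            cursor_out[t] = cursor
        return cursor_out
    raise ValueError(f"unknown model_kind {model_kind!r}")


def make_target(
    kind: str,
    n: int,
    seed: int = 0,
    amplitude: float = 10.0,
    period: float = 300.0,
    phase: float = 0.0,
    smoothing: int = 20,
) -> np.ndarray:
    """Target trajectory: a predictable sinusoid or a pseudorandom course.

    The pseudorandom course is uniform noise on ``[-amplitude, amplitude]``
    smoothed by a ``smoothing``-iteration moving average.
    """
    if kind == "sinusoid":
        t = np.arange(n)
        return amplitude * np.sin(2 * np.pi * t / period + phase)
    if kind == "pseudorandom":
        rng = np.random.default_rng(seed)
        raw = rng.uniform(-amplitude, amplitude, n + smoothing - 1)
        return np.convolve(raw, np.ones(smoothing) / smoothing, mode="valid")
    raise ValueError(f"unknown target kind {kind!r}")


@dataclass
class TrackingDataset:
    """A target trajectory, the observed cursor, and generator metadata."""

    target: np.ndarray
    cursor: np.ndarray
    dt: float = 0.016
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.cursor = np.asarray(self.cursor, dtype=float)
        if self.target.shape != self.cursor.shape or self.target.ndim != 1:
            raise ValueError("target and cursor must be 1-D series of equal length")
        if not (np.all(np.isfinite(self.target)) and np.all(np.isfinite(self.cursor))):
            raise ValueError("tracking data must be finite")


def generate_tracking_data(
    true_params: dict | None = None,
    target_kind: str = "sinusoid",
    noise_sd: float = 0.0,
    n: int = 900,
    seed: int = 0,
    model_kind: str = ONE_LEVEL,
) -> TrackingDataset:
    """Simulate a known control model tracking a target; record ground truth.

    With ``noise_sd = 0`` the cursor is the model's exact output; otherwise
    Gaussian observation noise is added.  Deterministic for a fixed seed.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if true_params is None:
        true_params = dict(TRUE_ONE_LEVEL if model_kind == ONE_LEVEL else TRUE_TWO_LEVEL)
    target = make_target(target_kind, n, seed=seed)
    clean = simulate_tracker(target, true_params, model_kind)
    rng = np.random.default_rng(seed + 1)
    cursor = clean + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else clean.copy()
    return TrackingDataset(
        target=target,
        cursor=cursor,
        meta=dict(
            true_params=dict(true_params),
            model_kind=model_kind,
            target_kind=target_kind,
            noise_sd=noise_sd,
            seed=seed,
        ),
    )


@dataclass
class FitResult:
    """Estimates and diagnostics from fitting a tracking model.

    ``rmse`` is the root-mean-square difference between the fitted model's
    simulated cursor and the observed cursor; ``correlation`` is the
    Pearson correlation between the two.
    """

    model_kind: str
    params: dict
    rmse: float
    correlation: float
    converged: bool
    n_starts: int
    n_evaluations: int
    delay_grid: tuple[int, ...]

    def summary(self) -> str:
        lines = [
            f"Tracking model fit: {self.model_kind}",
            "-" * 44,
            f"{'parameter':<12}{'estimate':>12}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<12}{v:>12.4f}")
        lines += [
            "-" * 44,
            f"{'RMSE':<12}{self.rmse:>12.6f}",
            f"{'correlation':<12}{self.correlation:>12.6f}",
            f"{'converged':<12}{str(self.converged):>12}",
            f"{'evaluations':<12}{self.n_evaluations:>12}",
        ]
        return "\n".join(lines)


class TrackingModel:
    """A control model of one tracking dataset, ready to be fitted.

    Parameters
    ----------
    data : TrackingDataset
        Target and observed cursor series.
    model_kind : str
        ``"one_level_position"`` (gain, slowing, delay) or
        ``"two_level_velocity"`` (gain and slowing per level, shared delay).
    """

    def __init__(self, data: TrackingDataset, model_kind: str = ONE_LEVEL):
        if model_kind not in PARAM_BOUNDS:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        self.data = data
        self.model_kind = model_kind
        self.param_names = list(PARAM_BOUNDS[model_kind])
        self.bounds = [PARAM_BOUNDS[model_kind][k] for k in self.param_names]

    def _objective(self, x: np.ndarray, delay: int) -> float:
        for xi, (lo, hi) in zip(x, self.bounds):
            if xi < lo or xi > hi:
                return 1e7
        params = dict(zip(self.param_names, x))
        params["delay"] = delay
        sim = simulate_tracker(
            self.data.target, params, self.model_kind, raise_on_divergence=False
        )
        rmse = float(np.sqrt(np.mean((sim - self.data.cursor) ** 2)))
        return rmse if math.isfinite(rmse) else 1e7

    def fit(
        self,
        n_starts: int = 8,
        delay_grid: tuple[int, ...] = DELAY_GRID,
        seed: int = 0,
        maxiter: int = 600,
    ) -> FitResult:
        """Minimize cursor RMSE by multistart Nelder--Mead over the
        continuous parameters, with the transport delay fitted on a small
        integer grid.

        The objective is simulation-defined and non-smooth in the delay,
        hence the derivative-free search.  If no start converges, the
        best-so-far parameters are returned with ``converged = False``.
        """
        rng = np.random.default_rng(seed)
        best = None
        n_eval = 0
        any_converged = False
        for delay in delay_grid:
            for _ in range(n_starts):
                x0 = np.array([rng.uniform(lo, hi) for lo, hi in self.bounds])
                res = minimize(
                    self._objective,
                    x0,
                    args=(delay,),
                    method="Nelder-Mead",
                    options=dict(maxiter=maxiter, fatol=1e-12, xatol=1e-9),
                )
                n_eval += res.nfev
                if best is None or res.fun < best[0]:
                    best = (res.fun, np.array(res.x), delay)
                    any_converged = any_converged or bool(res.success)
        rmse, x, delay = best
        params = dict(zip(self.param_names, (float(v) for v in x)))
        params["delay"] = int(delay)
        sim = simulate_tracker(self.data.target, params, self.model_kind,
                               raise_on_divergence=False)
        if np.std(sim) > 0 and np.std(self.data.cursor) > 0:
            corr = float(np.corrcoef(sim, self.data.cursor)[0, 1])
        else:
            corr = 0.0
        return FitResult(
            model_kind=self.model_kind,
            params=params,
            rmse=float(rmse),
            correlation=corr,
            converged=any_converged,
            n_starts=n_starts,
            n_evaluations=n_eval,
            delay_grid=tuple(delay_grid),
        )


def fit_unit(
    data: TrackingDataset,
    model_kind: str = ONE_LEVEL,
    **fit_kwargs,
) -> FitResult:
    """Functional wrapper: ``TrackingModel(data, model_kind).fit(...)``."""
    return TrackingModel(data, model_kind).fit(**fit_kwargs)
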