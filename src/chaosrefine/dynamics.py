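"""Benchmark dynamical-system simulators.

Generates labelled 1-D source signals by integrating small ODE systems with a
classical fixed-step fourth-order Runge-Kutta scheme and observing a single
state coordinate.  Three benchmark systems are built in:

* **Lorenz** (3rd order, chaotic) — the standard convective-roll model with
  sigma=10, rho=28, beta=8/3,

  .. math::
      \\dot x_1 = -\\sigma x_1 + \\sigma x_2,\\quad
      \\dot x_2 = \\rho x_1 - x_2 - x_1 x_3,\\quad
      \\dot x_3 = -\\beta x_3 + x_1 x_2 .

* **Rössler** (3rd order, chaotic) — ``x' = -y - z, y' = x + a y,
  z' = b + z (x - c)`` with a=b=0.2, c=5.7.

* **Linear oscillator** (2nd order, non-chaotic) — ``x'' + 2 zeta omega x' +
  omega^2 x = 0``; undamped (zeta=0) by default, so trajectories are pure
  sinusoids whose amplitude and phase are fixed by the initial condition.

The observed coordinate (the first state variable by default) is the source
signal for the downstream refinement pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import NumericalBlowupError

Label = str  # "chaotic" | "non-chaotic" | "unknown"


@dataclass(frozen=True)
class SystemSpec:
    """An autonomous ODE system with a ground-truth chaotic/non-chaotic label.

    Attributes
    ----------
    name : str
        Identifier of the system (e.g. ``"lorenz"``).
    order : int
        State dimension M (2 for the oscillator, 3 for Lorenz/Rössler).
    parameters : dict
        Named real constants of the state equations.
    chaotic : bool
        Ground-truth label of the dynamics under these parameters.
    derivative_rule : callable
        Map ``f(state) -> d(state)/dt`` for a length-``order`` state vector.
    """

    name: str
    order: int
    parameters: dict[str, float]
    chaotic: bool
    derivative_rule: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __post_init__(self):
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")

    @property
    def label(self) -> Label:
        return "chaotic" if self.chaotic else "non-chaotic"


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integration settings.

    ``transient_discard`` initial samples are dropped so that the retained
    window starts on (or near) the attractor.
    """

    dt: float
    n_samples: int
    initial_state: tuple[float, ...]
    transient_discard: int = 0
    method: str = "rk4"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.transient_discard < 0:
            raise ValueError("transient_discard must be >= 0")
        if self.method != "rk4":
            raise ValueError(f"unsupported integration method {self.method!r}")


@dataclass
class SignalSeries:
    """A named, labelled 1-D sample sequence with its sampling step."""

    samples: np.ndarray
    dt: float
    name: str
    label: Label = "unknown"
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    def __len__(self) -> int:
        return self.samples.size


# ---------------------------------------------------------------------------
# Built-in systems

def lorenz(sigma: float = 10.0, rho: float = 28.0, beta: float = 8.0 / 3.0) -> SystemSpec:
    """The Lorenz system; chaotic at the classical parameters."""

    def deriv(state: np.ndarray) -> np.ndarray:
        x1, x2, x3 = state
        return np.array([
            -sigma * x1 + sigma * x2,
            rho * x1 - x2 - x1 * x3,
            -beta * x3 + x1 * x2,
        ])

    return SystemSpec("lorenz", 3, {"sigma": sigma, "rho": rho, "beta": beta},
                      chaotic=True, derivative_rule=deriv)


def rossler(a: float = 0.2, b: float = 0.2, c: float = 5.7) -> SystemSpec:
    """The Rössler system; chaotic at the canonical a=b=0.2, c=5.7."""

    def deriv(state: np.ndarray) -> np.ndarray:
        x, y, z = state
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    return SystemSpec("rossler", 3, {"a": a, "b": b, "c": c},
                      chaotic=True, derivative_rule=deriv)


def linear_oscillator(omega: float = 2.0 * math.pi, zeta: float = 0.0) -> SystemSpec:
    """A (possibly damped) linear harmonic oscillator; never chaotic.

    The default natural frequency omega = 2*pi gives a period of exactly one
    time unit, i.e. 100 samples at the default dt = 0.01.
    """

    def deriv(state: np.ndarray) -> np.ndarray:
        x, v = state
        return np.array([v, -2.0 * zeta * omega * v - omega**2 * x])

    return SystemSpec("linear_oscillator", 2, {"omega": omega, "zeta": zeta},
                      chaotic=False, derivative_rule=deriv)


SYSTEMS: dict[str, Callable[[], SystemSpec]] = {
    "lorenz": lorenz,
    "rossler": rossler,
    "linear_oscillator": linear_oscillator,
}

#: Default sampling step per system.  Chosen so that a 1000-sample window
#: spans several characteristic oscillations (Lorenz ~0.7 t.u./oscillation,
#: Rössler ~5.9 t.u./orbit, oscillator 1 t.u./period).
DEFAULT_DT: dict[str, float] = {
    "lorenz": 0.01,
    "rossler": 0.05,
    "linear_oscillator": 0.01,
}

#: Reference initial states used (with seeded jitter) for corpus generation.
REFERENCE_INITIAL_STATE: dict[str, tuple[float, ...]] = {
    "lorenz": (1.0, 1.0, 1.0),
    "rossler": (1.0, 1.0, 0.0),
    "linear_oscillator": (1.0, 0.0),
}

#: Transient samples discarded before the retained window starts.
DEFAULT_TRANSIENT = 1000


# ---------------------------------------------------------------------------
# Integration

def system_derivative(spec: SystemSpec, state: Sequence[float]) -> np.ndarray:
    """Evaluate the state-derivative map f(state) of ``spec``.

    Pure and deterministic; raises ``ValueError`` on a dimension mismatch.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.order,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({spec.order},) for {spec.name}")
    return spec.derivative_rule(state)


def _rk4_step(f: Callable[[np.ndarray], np.ndarray], state: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(state)
    k2 = f(state + 0.5 * dt * k1)
    k3 = f(state + 0.5 * dt * k2)
    k4 = f(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(spec: SystemSpec, config: IntegratorConfig, observe_index: int = 0,
              name: str | None = None) -> SignalSeries:
    """Integrate ``spec`` and return the observed coordinate as a signal.

    The state is advanced with classical RK4 at fixed step ``config.dt``; the
    first ``config.transient_discard`` samples are dropped and the next
    ``config.n_samples`` values of coordinate ``observe_index`` are returned.
    Sample k of the output is the state at time ``(transient_discard + k)*dt``
    (the initial state itself is sample 0 of the undiscarded run).

    Raises
    ------
    NumericalBlowupError
        If the state becomes non-finite; the error names the step index.
    """
    if not 0 <= observe_index < spec.order:
        raise ValueError(f"observe_index {observe_index} out of range for order {spec.order}")
    state = np.asarray(config.initial_state, dtype=float)
    if state.shape != (spec.order,):
        raise ValueError(
            f"initial_state has length {state.size}, expected {spec.order}")

    total = config.transient_discard + config.n_samples
    out = np.empty(config.n_samples)
    for k in range(total):
        if not np.all(np.isfinite(state)):
            raise NumericalBlowupError(k)
        if k >= config.transient_discard:
            out[k - config.transient_discard] = state[observe_index]
        state = _rk4_step(spec.derivative_rule, state, config.dt)

    return SignalSeries(
        samples=out,
        dt=config.dt,
        name=name or spec.name,
        label=spec.label,
        source={
            "system": spec.name,
            "parameters": dict(spec.parameters),
            "order": spec.order,
            "dt": config.dt,
            "n_samples": config.n_samples,
            "transient_discard": config.transient_discard,
            "initial_state": [float(v) for v in config.initial_state],
            "observe_index": observe_index,
            "method": config.method,
        },
    )


def generate_corpus(specs: Sequence[SystemSpec], per_system: int, seed: int,
                    n_samples: int = 1000, jitter: float = 0.5,
                    transient_discard: int = DEFAULT_TRANSIENT) -> list[SignalSeries]:
    """Generate ``per_system`` labelled signals per system spec.

    Initial states are the per-system reference state plus seeded uniform
    jitter in ``[-jitter, +jitter]`` per coordinate, so series from the same
    system differ only in their initial condition.  Reproducible for a fixed
    seed.
    """
    if not specs:
        raise ValueError("specs must be a non-empty list")
    if per_system < 1:
        raise ValueError("per_system must be >= 1")
    rng = np.random.default_rng(seed)
    corpus: list[SignalSeries] = []
    for si, spec in enumerate(specs):
        ref = np.asarray(REFERENCE_INITIAL_STATE.get(spec.name, (1.0,) * spec.order))
        dt = DEFAULT_DT.get(spec.name, 0.01)
        for i in range(per_system):
            x0 = ref + rng.uniform(-jitter, jitter, size=spec.order)
            config = IntegratorConfig(dt=dt, n_samples=n_samples,
                                      initial_state=tuple(x0),
                                      transient_discard=transient_discard)
            # spec index in the name keeps series distinct when two specs
            # share a system name (e.g. oscillator parameter variants)
            corpus.append(integrate(spec, config, name=f"{spec.name}_{si}_{i:04d}"))
    return corpus
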