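"""Leaky integrate-and-fire (LIF) neuron dynamics with surrogate gradients.

The discrete-time LIF neuron keeps a membrane potential ``v`` that decays
geometrically toward the injected current::

    u_t = alpha * v_{t-1} + (1 - alpha) * I_t

where ``alpha = exp(-dt / tau_m)`` is the per-step retention of charge
(``dt = 1`` here, so the membrane time constant is absorbed into ``alpha``).
When the candidate potential ``u_t`` reaches the firing threshold the neuron
emits a binary spike and its potential is hard-reset to ``v_reset``; otherwise
the potential carries over unchanged.  The spike step function is not
differentiable, so training uses the *fast sigmoid* surrogate: the backward
pass pretends the spike was ``x / (1 + k |x|)`` (with ``x = u - v_th``) whose
derivative ``1 / (1 + k |x|)^2`` is smooth, positive and peaked at threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "SpikeTrain",
    "lif_step",
    "lif_sequence",
    "fast_sigmoid",
    "surrogate_gradient",
]


@dataclass(frozen=True)
class LIFParams:
    """Parameters of the discrete LIF neuron.

    Attributes
    ----------
    alpha : float
        Membrane decay per step, in (0, 1).  ``alpha = exp(-dt/tau_m)``.
    v_th : float
        Firing threshold (membrane-potential units).
    v_reset : float
        Potential immediately after a spike; must lie below ``v_th``.
    n_steps : int
        Number of discrete simulation steps ``T``.
    surrogate_slope : float
        Slope ``k`` of the fast-sigmoid surrogate used during backprop.
    """

    alpha: float = 0.95
    v_th: float = 1.0
    v_reset: float = 0.0
    n_steps: int = 25
    surrogate_slope: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.v_reset < self.v_th:
            raise ValueError(
                f"v_reset ({self.v_reset}) must be below v_th ({self.v_th})"
            )
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if not self.surrogate_slope > 0:
            raise ValueError(
                f"surrogate_slope must be positive, got {self.surrogate_slope}"
            )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "v_th": self.v_th,
            "v_reset": self.v_reset,
            "n_steps": self.n_steps,
            "surrogate_slope": self.surrogate_slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LIFParams":
        return cls(**d)


@dataclass
class LIFState:
    """Membrane potentials of a population of LIF neurons."""

    v: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not np.all(np.isfinite(self.v)):
            raise ValueError("membrane potentials must be finite")

    @classmethod
    def zeros(cls, n: int) -> "LIFState":
        return cls(v=np.zeros(n))


@dataclass
class SpikeTrain:
    """Binary firing record: one row per time step, one column per neuron."""

    spikes: np.ndarray  # (T, N) with entries in {0, 1}

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        vals = np.unique(self.spikes)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("spike entries must be exactly 0 or 1")

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[0]

    def rate(self) -> np.ndarray:
        """Mean spike count per neuron over the temporal window."""
        return self.spikes.mean(axis=0)


def lif_step(
    state: LIFState, input_current: np.ndarray, params: LIFParams
) -> tuple[LIFState, np.ndarray]:
    """Advance a LIF population by one Euler step.

    Order of operations is fixed: membrane update, threshold comparison
    (``>=``), then hard reset of the spiking neurons.

    Returns the new state and the binary spike vector.
    """
    current = np.asarray(input_current, dtype=float)
    if current.shape != state.v.shape:
        raise ValueError(
            f"input current shape {current.shape} does not match "
            f"state shape {state.v.shape}"
        )
    if not np.all(np.isfinite(current)):
        raise ValueError("input current must be finite")

    u = params.alpha * state.v + (1.0 - params.alpha) * current
    spikes = (u >= params.v_th).astype(float)
    v_next = np.where(spikes == 1.0, params.v_reset, u)
    return LIFState(v=v_next), spikes


def lif_sequence(
    input_currents: np.ndarray,
    params: LIFParams,
    initial_state: LIFState | None = None,
) -> tuple[SpikeTrain, LIFState]:
    """Run a LIF population for ``params.n_steps`` steps.

    ``input_currents`` is either a ``(T, N)`` matrix of per-step currents or a
    length-``N`` vector injected identically at every step (the rate-coding
    regime used by the hybrid model's head).
    """
    currents = np.asarray(input_currents, dtype=float)
    T = params.n_steps
    if currents.ndim == 1:
        currents = np.broadcast_to(currents, (T, currents.shape[0]))
    elif currents.ndim == 2:
        if currents.shape[0] != T:
            raise ValueError(
                f"input has {currents.shape[0]} steps but params.n_steps={T}"
            )
    else:
        raise ValueError("input_currents must be 1-D or 2-D")

    n = currents.shape[1]
    state = initial_state if initial_state is not None else LIFState.zeros(n)
    record = np.empty((T, n))
    for t in range(T):
        state, spikes = lif_step(state, currents[t], params)
        record[t] = spikes
    return SpikeTrain(spikes=record), state


def fast_sigmoid(x: np.ndarray | float, slope: float = 5.0) -> np.ndarray:
    """Fast sigmoid ``x / (1 + k|x|)``, the smooth relaxation of the spike step."""
    x = np.asarray(x, dtype=float)
    return x / (1.0 + slope * np.abs(x))


def surrogate_gradient(
    v_minus_th: np.ndarray | float, slope: float = 5.0
) -> np.ndarray:
    """Derivative of the fast sigmoid: ``1 / (1 + k|x|)^2``.

    Used in place of the spike step's derivative during backpropagation; the
    forward pass still emits hard {0, 1} spikes.  Positive, even in ``x``,
    maximal (=1) at threshold and strictly decreasing in ``|x|``.
    """
    if not slope > 0:
        raise ValueError(f"slope must be positive, got {slope}")
    x = np.asarray(v_minus_th, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return 1.0 / (1.0 + slope * np.abs(x)) ** 2
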