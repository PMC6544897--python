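"""Shared numerical machinery for the attention networks.

Both model variants minimise a total energy by noisy gradient descent in the
style of Hopfield and Tank: every sigmoidal unit carries a membrane energy
whose gradient yields leaky-integrator dynamics, competing populations carry
a winner-take-all (WTA) energy, and the state is advanced with an explicit
Euler step plus Gaussian noise.  Firing rates ``y`` and membrane potentials
``x`` are linked through a logistic activation ``y = f(x) = 1 / (1 +
exp(-m (x - s)))``; the Contents Network is linear (``y == x``), so its
membrane analogue is ``x**2 / 2``.

The Euler update follows the descent rule ``x(t) = x(t-1) - eta * dE/dy +
noise``: the gradient is taken with respect to the rate but applied to the
potential, which preserves the Lyapunov property (energy is non-increasing
for small steps at zero noise) because ``dy/dx = f'(x) >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "ModelParams",
    "NetworkState",
    "sigmoid",
    "sigmoid_inverse",
    "membrane_energy",
    "linear_membrane_energy",
    "wta_energy",
    "euler_step",
]

_EXP_CLIP = 500.0  # exp argument clip; beyond this the logistic saturates anyway


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the network dynamics.

    Attributes
    ----------
    sigmoid_slope, sigmoid_shift:
        Logistic slope ``m`` (dimensionless) and midpoint ``s`` (potential
        units) of the activation function.
    step_size:
        Euler step ``eta`` multiplying the gradient; absorbs the membrane
        time constant.
    noise_sd:
        Standard deviation of the zero-mean Gaussian noise added to every
        membrane potential each iteration (potential units).
    a_sn, a_kn:
        WTA normalisation weights (the soft "activities sum to one"
        constraint) for the Selection and Knowledge Networks.
    b_cn, b_kn:
        Matching/feedback weights: image-to-contents coupling and
        contents-to-knowledge coupling.
    rt_threshold:
        Rate threshold a Knowledge-Network unit must cross for the model to
        report an identification; the crossing iteration is the simulated
        reaction time.
    max_iters:
        Iteration budget before a run is flagged as timed out.
    """

    sigmoid_slope: float = 1.0
    sigmoid_shift: float = 0.0
    step_size: float = 0.05
    noise_sd: float = 0.0
    a_sn: float = 1.0
    a_kn: float = 1.0
    b_cn: float = 1.0
    b_kn: float = 1.0
    rt_threshold: float = 0.9
    max_iters: int = 5000

    def __post_init__(self) -> None:
        checks = {
            "sigmoid_slope": self.sigmoid_slope > 0,
            "step_size": self.step_size > 0,
            "noise_sd": self.noise_sd >= 0,
            "a_sn": self.a_sn >= 0,
            "a_kn": self.a_kn >= 0,
            "b_cn": self.b_cn >= 0,
            "b_kn": self.b_kn >= 0,
            "rt_threshold": 0 < self.rt_threshold < 1,
            "max_iters": self.max_iters >= 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid parameter value(s) for: {', '.join(bad)}")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class NetworkState:
    """Membrane potentials and firing rates of the three networks.

    ``x_sn``/``y_sn`` live on the grid of valid focus placements (one unit
    per top-left corner the focus window can take), ``x_cn`` is the M x M
    focus content (linear output, so no separate rate array), and
    ``x_kn``/``y_kn`` are the K template units.
    """

    x_sn: np.ndarray
    y_sn: np.ndarray
    x_cn: np.ndarray
    x_kn: np.ndarray
    y_kn: np.ndarray
    iteration: int = 0

    @property
    def y_cn(self) -> np.ndarray:
        """Contents-Network output; identical to its potential (linear unit)."""
        return self.x_cn

    def copy(self) -> "NetworkState":
        return NetworkState(
            x_sn=self.x_sn.copy(), y_sn=self.y_sn.copy(), x_cn=self.x_cn.copy(),
            x_kn=self.x_kn.copy(), y_kn=self.y_kn.copy(), iteration=self.iteration,
        )


def sigmoid(x, params: ModelParams):
    """Logistic activation ``1 / (1 + exp(-m (x - s)))``, overflow-safe."""
    z = np.clip(params.sigmoid_slope * (np.asarray(x, dtype=float) - params.sigmoid_shift),
                -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(-z))


def sigmoid_inverse(y, params: ModelParams):
    """Potential producing rate ``y``: ``s + logit(y) / m``.  Requires 0 < y < 1."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("sigmoid_inverse requires rates strictly inside (0, 1)")
    return params.sigmoid_shift + np.log(y / (1.0 - y)) / params.sigmoid_slope


def membrane_energy(y, params: ModelParams) -> float:
    """Sum over units of the integral of the inverse activation, 0 to y.

    Closed form of ``sum_i int_0^{y_i} f^{-1}(z) dz`` for the logistic:
    ``s*y + (y ln y + (1-y) ln(1-y)) / m`` per unit (the binary-entropy term
    is the antiderivative of the logit).  Diverges at the boundary, so rates
    must lie strictly in (0, 1).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("membrane energy diverges at rates 0 or 1")
    ent = y * np.log(y) + (1.0 - y) * np.log1p(-y)
    return float(np.sum(params.sigmoid_shift * y + ent / params.sigmoid_slope))


def linear_membrane_energy(x) -> float:
    """Membrane analogue for linear units: ``sum x**2 / 2``."""
    x = np.asarray(x, dtype=float)
    return float(0.5 * np.sum(x * x))


def wta_energy(y, inputs, a: float, b: float, sign: int = +1) -> float:
    """Winner-take-all energy ``a/2 ((sum y) - 1)^2 - sign * b * sum(y * I)``.

    ``sign=+1`` gives the softmax form (largest input wins); ``sign=-1``
    flips the input term into a loser-take-all (smallest input wins), the
    form the prediction-error variant needs.
    """
    y = np.asarray(y, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    if y.shape != inputs.shape:
        raise ValueError(f"y and inputs must have the same shape, got {y.shape} vs {inputs.shape}")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 (winner-take-all) or -1 (loser-take-all)")
    return float(0.5 * a * (y.sum() - 1.0) ** 2 - sign * b * np.sum(y * inputs))


class DivergenceError(RuntimeError):
    """Raised when a gradient or state stops being finite."""


def euler_step(state: NetworkState, gradients, params: ModelParams,
               rng: np.random.Generator) -> NetworkState:
    """One noisy Euler update ``x <- x - eta * g + N(0, noise_sd)``.

    ``gradients`` is the triple ``(g_sn, g_cn, g_kn)`` of energy gradients
    with respect to the Selection rates, Contents potentials and Knowledge
    rates.  Rates are recomputed from the new potentials; the Contents
    Network is linear so its rate is its potential.  ``rng`` is the only
    source of randomness.
    """
    g_sn, g_cn, g_kn = (np.asarray(g, dtype=float) for g in gradients)
    if g_sn.shape != state.x_sn.shape or g_cn.shape != state.x_cn.shape \
            or g_kn.shape != state.x_kn.shape:
        raise ValueError("gradient shapes do not match state shapes")
    if not (np.all(np.isfinite(g_sn)) and np.all(np.isfinite(g_cn))
            and np.all(np.isfinite(g_kn))):
        raise DivergenceError(f"non-finite gradient at iteration {state.iteration}")
    eta, sd = params.step_size, params.noise_sd
    x_sn = state.x_sn - eta * g_sn
    x_cn = state.x_cn - eta * g_cn
    x_kn = state.x_kn - eta * g_kn
    if sd > 0:
        x_sn = x_sn + rng.normal(0.0, sd, size=x_sn.shape)
        x_cn = x_cn + rng.normal(0.0, sd, size=x_cn.shape)
        x_kn = x_kn + rng.normal(0.0, sd, size=x_kn.shape)
    return NetworkState(
        x_sn=x_sn, y_sn=sigmoid(x_sn, params), x_cn=x_cn,
        x_kn=x_kn, y_kn=sigmoid(x_kn, params), iteration=state.iteration + 1,
    )
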