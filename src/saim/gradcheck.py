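"""Finite-difference verification of the analytic energy gradients.

Checks that the gradients each model integrates are exact derivatives of
its assembled total energy, by central differences on random small states.
This is the package's own self-check (exposed through the command line);
the test suite carries an independently written oracle.
"""

from __future__ import annotations

import numpy as np

from .dynamics import ModelParams, NetworkState, sigmoid_inverse
from .em import EMModel
from .pe import PEModel
from .stimuli import TemplateSet, compose_scene, make_template

__all__ = ["random_small_state", "finite_difference_gradients", "gradient_check"]


def _small_problem(params: ModelParams):
    ts = TemplateSet(
        (make_template("plus", 3), make_template("two", 3)),
        ("plus", "two"), normalize="none",
    )
    stim = compose_scene(ts, [("plus", 1, 1)], 5)
    return stim, ts


def random_small_state(rng: np.random.Generator, params: ModelParams,
                       n_placements: int = 3, m: int = 3, k: int = 2) -> NetworkState:
    """A random state away from sigmoid saturation, on the N=5/M=3/K=2 problem."""
    y_sn = rng.uniform(0.2, 0.8, (n_placements, n_placements))
    y_kn = rng.uniform(0.2, 0.8, k)
    return NetworkState(
        x_sn=sigmoid_inverse(y_sn, params), y_sn=y_sn,
        x_cn=rng.normal(0.0, 1.0, (m, m)),
        x_kn=sigmoid_inverse(y_kn, params), y_kn=y_kn,
    )


def finite_difference_gradients(model, state: NetworkState, params: ModelParams,
                                h: float = 1e-6):
    """Central differences of the model's total energy in (y_sn, x_cn, y_kn)."""
    arrays = {"y_sn": state.y_sn.copy(), "x_cn": state.x_cn.copy(),
              "y_kn": state.y_kn.copy()}

    def energy(a):
        st = NetworkState(
            x_sn=sigmoid_inverse(a["y_sn"], params), y_sn=a["y_sn"],
            x_cn=a["x_cn"],
            x_kn=sigmoid_inverse(a["y_kn"], params), y_kn=a["y_kn"],
        )
        return model.total_energy(st)

    grads = []
    for name in ("y_sn", "x_cn", "y_kn"):
        g = np.zeros_like(arrays[name])
        for idx in np.ndindex(g.shape):
            vals = []
            for sign in (+1, -1):
                a = {k: v.copy() for k, v in arrays.items()}
                a[name][idx] += sign * h
                vals.append(energy(a))
            g[idx] = (vals[0] - vals[1]) / (2.0 * h)
        grads.append(g)
    return tuple(grads)


def gradient_check(n_states: int = 50, seed: int = 0, rtol: float = 1e-6,
                   params: ModelParams | None = None) -> dict[str, float]:
    """Worst relative gradient error per model over random small states."""
    if params is None:
        params = ModelParams(sigmoid_slope=1.3, sigmoid_shift=0.2, a_sn=0.7,
                             a_kn=1.1, b_cn=0.9, b_kn=0.6)
    stim, ts = _small_problem(params)
    rng = np.random.default_rng(seed)
    worst = {}
    for name, cls in (("em", EMModel), ("pe", PEModel)):
        model = cls(stim, ts, params)
        err = 0.0
        for _ in range(n_states):
            st = random_small_state(rng, params)
            analytic = model.gradients(st)
            numeric = finite_difference_gradients(model, st, params)
            for ga, gn in zip(analytic, numeric):
                rel = np.linalg.norm(ga - gn) / (np.linalg.norm(gn) + 1e-300)
                err = max(err, float(rel))
        worst[name] = err
    worst["passed"] = float(all(v <= rtol for k, v in worst.items() if k != "passed"))
    return worst
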