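import numpy as np
import pytest

from saim import ModelParams, TemplateSet, compose_scene, make_template


@pytest.fixture
def tiny_templates():
    """3x3 plus and two with raw binary weights."""
    return TemplateSet(
        (make_template("plus", 3), make_template("two", 3)),
        ("plus", "two"), normalize="none",
    )


@pytest.fixture
def tiny_stimulus(tiny_templates):
    """5x5 scene with a single plus at (1, 1)."""
    return compose_scene(tiny_templates, [("plus", 1, 1)], 5, expected_winner="plus")


@pytest.fixture
def generic_params():
    """Mid-range parameters keeping all states away from saturation."""
    return ModelParams(sigmoid_slope=1.3, sigmoid_shift=0.2, a_sn=0.7, a_kn=1.1,
                       b_cn=0.9, b_kn=0.6, step_size=0.01)


def random_state(rng, params, n_placements=3, m=3, k=2):
    """Random small network state with consistent rates and potentials."""
    from saim import NetworkState, sigmoid_inverse

    y_sn = rng.uniform(0.2, 0.8, (n_placements, n_placements))
    y_kn = rng.uniform(0.2, 0.8, k)
    return NetworkState(
        x_sn=sigmoid_inverse(y_sn, params), y_sn=y_sn,
        x_cn=rng.normal(0.0, 1.0, (m, m)),
        x_kn=sigmoid_inverse(y_kn, params), y_kn=y_kn,
    )


def finite_difference(energy_fn, state, params, h=1e-6):
    """Central differences of a total energy in (y_sn, x_cn, y_kn).

    Written independently of the package's own gradient checker so the two
    derivations cross-validate each other.
    """
    from saim import NetworkState, sigmoid_inverse

    arrays = {"y_sn": state.y_sn.copy(), "x_cn": state.x_cn.copy(),
              "y_kn": state.y_kn.copy()}

    def energy(a):
        st = NetworkState(
            x_sn=sigmoid_inverse(a["y_sn"], params), y_sn=a["y_sn"],
            x_cn=a["x_cn"],
            x_kn=sigmoid_inverse(a["y_kn"], params), y_kn=a["y_kn"],
        )
        return energy_fn(st)

    out = []
    for name in ("y_sn", "x_cn", "y_kn"):
        g = np.zeros_like(arrays[name])
        for idx in np.ndindex(g.shape):
            up = {k: v.copy() for k, v in arrays.items()}
            dn = {k: v.copy() for k, v in arrays.items()}
            up[name][idx] += h
            dn[name][idx] -= h
            g[idx] = (energy(up) - energy(dn)) / (2.0 * h)
        out.append(g)
    return tuple(out)
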