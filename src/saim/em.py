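"""Excitatory-matching model.

The three networks — Selection (a winner-take-all over focus placements),
Contents (the focus-of-attention bitmap) and Knowledge (template units) —
jointly minimise one energy.  The Selection Network gates image patches
into the Contents Network through Sigma-pi (multiplicative) synapses, the
Knowledge Network scores the focus content against stored templates, and
both top-down couplings (templates into the focus, focus correlation into
the selection layer) enter the gradients with negative sign: matched
representations are *boosted*, which is what makes this the excitatory
variant.

Selection units are indexed by valid top-left focus placements, so the
Selection layer is (N-M+1) x (N-M+1) and every Sigma-pi product pairs a
placement with a pixel inside its window; no out-of-range index arises.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dynamics import (ModelParams, NetworkState, linear_membrane_energy,
                       membrane_energy, sigmoid_inverse, wta_energy)
from .engine import SimulationResult, simulate
from .stimuli import Stimulus, TemplateSet

__all__ = [
    "template_match",
    "sigma_pi_input",
    "selection_drive",
    "EMModel",
    "em_gradients",
    "em_total_energy",
    "run_em",
    "log_density_components",
]


def image_patches(image: np.ndarray, m: int) -> np.ndarray:
    """All M x M windows of the image as a (P, P, M, M) view, P = N - M + 1."""
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    if image.ndim != 2 or image.shape[1] != n:
        raise ValueError("image must be square")
    if not 1 <= m <= n:
        raise ValueError(f"window size {m} does not fit image size {n}")
    return sliding_window_view(image, (m, m))


def template_match(x_cn: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """Scalar product of the focus content with each template's weights."""
    x_cn = np.asarray(x_cn, dtype=float)
    if x_cn.shape != (templates.size, templates.size):
        raise ValueError(
            f"focus content shape {x_cn.shape} does not match template size {templates.size}"
        )
    return np.einsum("ij,kij->k", x_cn, templates.weight_array())


def sigma_pi_input(y_sn: np.ndarray, stimulus: Stimulus | np.ndarray, m: int) -> np.ndarray:
    """Selection-gated image patch: ``I[m,n] = sum_rc y_sn[r,c] * image[r+m, c+n]``.

    With the selection rates concentrated on one placement this is exactly
    that placement's M x M window; in general it is the selection-weighted
    average of all windows (the translation-invariant mapping realised by
    Sigma-pi gating).
    """
    image = stimulus.image if isinstance(stimulus, Stimulus) else np.asarray(stimulus)
    patches = image_patches(image, m)
    y_sn = np.asarray(y_sn, dtype=float)
    if y_sn.shape != patches.shape[:2]:
        raise ValueError(
            f"selection shape {y_sn.shape} does not match placement grid {patches.shape[:2]}"
        )
    return np.einsum("rc,rcmn->mn", y_sn, patches)


def selection_drive(x_cn: np.ndarray, stimulus: Stimulus | np.ndarray) -> np.ndarray:
    """Correlation of the focus content with every image window.

    ``D[r,c] = sum_mn x_cn[m,n] * image[r+m, c+n]`` — the top-down input
    telling the Selection Network how well each placement matches the
    current focus content.
    """
    image = stimulus.image if isinstance(stimulus, Stimulus) else np.asarray(stimulus)
    x_cn = np.asarray(x_cn, dtype=float)
    patches = image_patches(image, x_cn.shape[0])
    return np.einsum("mn,rcmn->rc", x_cn, patches)


def initial_state(stimulus: Stimulus, templates: TemplateSet,
                  params: ModelParams) -> NetworkState:
    """Unbiased start: equal template rates (1/K), equal selection rates
    (1/#placements), and the focus set to the mean of the template weights."""
    k, m, n = templates.n_templates, templates.size, stimulus.size
    p = n - m + 1
    y_kn = np.full(k, 1.0 / k)
    y_sn = np.full((p, p), 1.0 / (p * p))
    return NetworkState(
        x_sn=sigmoid_inverse(y_sn, params), y_sn=y_sn,
        x_cn=templates.weight_array().mean(axis=0),
        x_kn=sigmoid_inverse(y_kn, params), y_kn=y_kn,
    )


class EMModel:
    """Bundles stimulus, templates and parameters; precomputes patch views."""

    name = "em"

    def __init__(self, stimulus: Stimulus, templates: TemplateSet, params: ModelParams):
        if stimulus.size < templates.size:
            raise ValueError("image smaller than templates")
        self.stimulus = stimulus
        self.templates = templates
        self.params = params
        self.patches = image_patches(stimulus.image, templates.size)
        self.weights = templates.weight_array()

    def initial_state(self) -> NetworkState:
        return initial_state(self.stimulus, self.templates, self.params)

    def derived(self, state: NetworkState):
        i_cn = np.einsum("rc,rcmn->mn", state.y_sn, self.patches)
        x_temp = np.einsum("ij,kij->k", state.x_cn, self.weights)
        return i_cn, x_temp

    def gradients(self, state: NetworkState):
        """Analytic energy gradients for the three networks.

        Selection: leak + normalisation - focus/image correlation.
        Contents:  leak - gated image input - template feedback.
        Knowledge: leak + normalisation - template match.
        The negative signs on the inter-network terms are the excitatory
        feedback that defines this variant.
        """
        p = self.params
        i_cn, x_temp = self.derived(state)
        corr = np.einsum("mn,rcmn->rc", state.x_cn, self.patches)
        g_sn = state.x_sn + p.a_sn * (state.y_sn.sum() - 1.0) - p.b_cn * corr
        g_cn = (state.x_cn - p.b_cn * i_cn
                - p.b_kn * np.einsum("k,kij->ij", state.y_kn, self.weights))
        g_kn = state.x_kn + p.a_kn * (state.y_kn.sum() - 1.0) - p.b_kn * x_temp
        for g, net in ((g_sn, "Selection"), (g_cn, "Contents"), (g_kn, "Knowledge")):
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in the {net} Network")
        return g_sn, g_cn, g_kn

    def energy_components(self, state: NetworkState) -> dict[str, float]:
        p = self.params
        i_cn, x_temp = self.derived(state)
        return {
            "membrane": (membrane_energy(state.y_sn, p) + membrane_energy(state.y_kn, p)
                         + linear_membrane_energy(state.x_cn)),
            "selection": 0.5 * p.a_sn * (state.y_sn.sum() - 1.0) ** 2,
            "contents": -p.b_cn * float(np.sum(state.x_cn * i_cn)),
            "knowledge": wta_energy(state.y_kn, x_temp, p.a_kn, p.b_kn, sign=+1),
        }

    def total_energy(self, state: NetworkState) -> float:
        return float(sum(self.energy_components(state).values()))

    def input_drives(self, state: NetworkState):
        """Signed b-weighted inter-network drives for Selection and Knowledge.

        These are the matching/feedback input terms of the gradients —
        excluding leak and the a-weighted normalisation, which stand in for
        interneuron activity in neuronal-response summaries.
        """
        p = self.params
        _, x_temp = self.derived(state)
        drive_sn = p.b_cn * np.einsum("mn,rcmn->rc", state.x_cn, self.patches)
        drive_kn = p.b_kn * x_temp
        return drive_sn, drive_kn


def em_gradients(state: NetworkState, stimulus: Stimulus, templates: TemplateSet,
                 params: ModelParams):
    """Module-level convenience wrapper around :meth:`EMModel.gradients`."""
    return EMModel(stimulus, templates, params).gradients(state)


def em_total_energy(state: NetworkState, stimulus: Stimulus, templates: TemplateSet,
                    params: ModelParams) -> float:
    return EMModel(stimulus, templates, params).total_energy(state)


def log_density_components(state: NetworkState, stimulus: Stimulus,
                           templates: TemplateSet, params: ModelParams) -> dict[str, float]:
    """Generative-model reading of the energies.

    Under a Gibbs measure the (non-membrane) energy components are negated
    log-densities: the Contents term is the log-likelihood of the visual
    field, the Selection and Knowledge normalisation quadratics are sparse
    full priors, and the template-feedback term is the empirical prior on
    the focus content given the template units.
    """
    comps = EMModel(stimulus, templates, params).energy_components(state)
    i_cn, x_temp = EMModel(stimulus, templates, params).derived(state)
    return {
        "log_likelihood": -comps["contents"],
        "sn_prior": -comps["selection"],
        "cn_empirical_prior": params.b_kn * float(np.dot(state.y_kn, x_temp)),
        "kn_prior": -0.5 * params.a_kn * (state.y_kn.sum() - 1.0) ** 2,
    }


def run_em(stimulus: Stimulus, templates: TemplateSet, params: ModelParams,
           seed: int, **kwargs) -> SimulationResult:
    """Integrate the excitatory-matching model from the unbiased start."""
    return simulate(EMModel(stimulus, templates, params), seed, **kwargs)
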