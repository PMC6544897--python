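"""Prediction-error model.

Same three networks, same integrator, but the generative model is Gaussian:
the inter-network energies become half-squared prediction errors.  A
contents-level error field compares the selection-gated image patch with
the focus content, and a knowledge-level error field compares the focus
content with each template unit's prediction ``y_k * w_k``.  Top-down
influence is now carried by subtracting predictions — inhibitory feedback —
and the winner-take-all priors act as loser-take-all on the errors: the
template that best *predicts* the focus wins.

The gradients are the exact derivatives of the assembled free energy; a
finite-difference oracle in the test suite pins them down.  Note that the
knowledge-unit gradient carries ``- b_kn * sum(eps_kn * w)``: the error
field depends on ``y_k`` through the subtracted prediction, so the chain
rule contributes ``-w``, and it is this sign that makes the best-predicting
unit rise (its rising prediction eats its own error).
"""

from __future__ import annotations

import numpy as np

from .dynamics import (ModelParams, NetworkState, linear_membrane_energy,
                       membrane_energy)
from .em import image_patches, initial_state
from .engine import SimulationResult, simulate
from .stimuli import Stimulus, TemplateSet

__all__ = ["PEModel", "prediction_errors", "pe_gradients", "pe_total_energy", "run_pe"]


def prediction_errors(state: NetworkState, stimulus: Stimulus,
                      templates: TemplateSet):
    """Contents-level and knowledge-level prediction-error fields.

    ``eps_cn[m,n] = (gated image patch)[m,n] - x_cn[m,n]`` (shape M x M) and
    ``eps_kn[k,i,j] = x_cn[i,j] - y_kn[k] * w_k[i,j]`` (shape K x M x M).
    """
    return PEModel(stimulus, templates, ModelParams()).errors(state)


class PEModel:
    """Prediction-error variant sharing the excitatory model's geometry."""

    name = "pe"

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

    def errors(self, state: NetworkState):
        i_cn = np.einsum("rc,rcmn->mn", state.y_sn, self.patches)
        eps_cn = i_cn - state.x_cn
        eps_kn = state.x_cn[None, :, :] - state.y_kn[:, None, None] * self.weights
        return eps_cn, eps_kn

    def gradients(self, state: NetworkState):
        p = self.params
        eps_cn, eps_kn = self.errors(state)
        g_sn = (state.x_sn + p.a_sn * (state.y_sn.sum() - 1.0)
                + p.b_cn * np.einsum("mn,rcmn->rc", eps_cn, self.patches))
        g_cn = state.x_cn - p.b_cn * eps_cn + p.b_kn * eps_kn.sum(axis=0)
        g_kn = (state.x_kn + p.a_kn * (state.y_kn.sum() - 1.0)
                - p.b_kn * np.einsum("kij,kij->k", eps_kn, self.weights))
        for g, net in ((g_sn, "Selection"), (g_cn, "Contents"), (g_kn, "Knowledge")):
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in the {net} Network")
        return g_sn, g_cn, g_kn

    def energy_components(self, state: NetworkState) -> dict[str, float]:
        p = self.params
        eps_cn, eps_kn = self.errors(state)
        return {
            "membrane": (membrane_energy(state.y_sn, p) + membrane_energy(state.y_kn, p)
                         + linear_membrane_energy(state.x_cn)),
            "selection": 0.5 * p.a_sn * (state.y_sn.sum() - 1.0) ** 2,
            "contents_error": 0.5 * p.b_cn * float(np.sum(eps_cn ** 2)),
            "knowledge_prior": 0.5 * p.a_kn * (state.y_kn.sum() - 1.0) ** 2,
            "knowledge_error": 0.5 * p.b_kn * float(np.sum(eps_kn ** 2)),
        }

    def total_energy(self, state: NetworkState) -> float:
        return float(sum(self.energy_components(state).values()))

    def input_drives(self, state: NetworkState):
        """Signed error-mediated drives for Selection and Knowledge units."""
        p = self.params
        eps_cn, eps_kn = self.errors(state)
        drive_sn = p.b_cn * np.einsum("mn,rcmn->rc", eps_cn, self.patches)
        drive_kn = p.b_kn * np.einsum("kij,kij->k", eps_kn, self.weights)
        return drive_sn, drive_kn


def pe_gradients(state: NetworkState, stimulus: Stimulus, templates: TemplateSet,
                 params: ModelParams):
    return PEModel(stimulus, templates, params).gradients(state)


def pe_total_energy(state: NetworkState, stimulus: Stimulus, templates: TemplateSet,
                    params: ModelParams) -> float:
    return PEModel(stimulus, templates, params).total_energy(state)


def run_pe(stimulus: Stimulus, templates: TemplateSet, params: ModelParams,
           seed: int, **kwargs) -> SimulationResult:
    """Integrate the prediction-error model from the unbiased start."""
    return simulate(PEModel(stimulus, templates, params), seed, **kwargs)
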