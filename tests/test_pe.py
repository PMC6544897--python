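import numpy as np
import pytest

from saim import (ModelParams, NetworkState, TemplateSet, compose_scene,
                  pe_gradients, pe_total_energy, prediction_errors,
                  reference_params, reference_templates, run_em, run_pe,
                  sigmoid_inverse)
from saim.pe import PEModel
from saim.stimuli import reference_scenes

from conftest import finite_difference, random_state


def naive_errors(state, image, weights):
    """Loop reference for both prediction-error fields."""
    p, m, k = state.y_sn.shape[0], state.x_cn.shape[0], len(weights)
    eps_cn = -state.x_cn.copy()
    for a in range(m):
        for b in range(m):
            for r in range(p):
                for c in range(p):
                    eps_cn[a, b] += image[r + a, c + b] * state.y_sn[r, c]
    eps_kn = np.stack([state.x_cn - state.y_kn[i] * weights[i] for i in range(k)])
    return eps_cn, eps_kn


class TestPredictionErrors:
    def test_perfect_contents_prediction(self, tiny_stimulus, tiny_templates,
                                         generic_params):
        from saim import sigma_pi_input

        st = random_state(np.random.default_rng(0), generic_params)
        st.x_cn = sigma_pi_input(st.y_sn, tiny_stimulus, 3)
        eps_cn, _ = prediction_errors(st, tiny_stimulus, tiny_templates)
        np.testing.assert_allclose(eps_cn, 0.0, atol=1e-12)

    def test_perfect_template_prediction(self, tiny_stimulus, tiny_templates,
                                         generic_params):
        st = random_state(np.random.default_rng(1), generic_params)
        st.y_kn = np.array([0.999, 0.5])
        st.x_cn = st.y_kn[0] * tiny_templates.weights[0]
        _, eps_kn = prediction_errors(st, tiny_stimulus, tiny_templates)
        np.testing.assert_allclose(eps_kn[0], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_loops(self, seed, tiny_stimulus, tiny_templates,
                                 generic_params):
        st = random_state(np.random.default_rng(seed), generic_params)
        eps_cn, eps_kn = prediction_errors(st, tiny_stimulus, tiny_templates)
        ref_cn, ref_kn = naive_errors(st, tiny_stimulus.image, tiny_templates.weights)
        np.testing.assert_allclose(eps_cn, ref_cn)
        np.testing.assert_allclose(eps_kn, ref_kn)


class TestPeGradients:
    def test_vanished_errors_leave_leak_terms(self):
        # all-ones image and template: a uniform state predicts its own input,
        # so with the normalisation weights off only the leaks remain
        ones = np.ones((3, 3))
        ts = TemplateSet((ones,), ("blob",), normalize="none")
        stim = compose_scene(ts, [("blob", 1, 1)], 5)
        stim.image[:] = 1.0
        p = ModelParams(a_sn=0.0, a_kn=0.0, b_cn=0.7, b_kn=0.4)
        u = 0.05
        y_sn = np.full((3, 3), u)
        total = float(y_sn.sum())
        st = NetworkState(x_sn=sigmoid_inverse(y_sn, p), y_sn=y_sn,
                          x_cn=np.full((3, 3), total),
                          x_kn=sigmoid_inverse(np.array([total]), p),
                          y_kn=np.array([total]))
        g_sn, g_cn, g_kn = pe_gradients(st, stim, ts, p)
        np.testing.assert_allclose(g_sn, st.x_sn)
        np.testing.assert_allclose(g_cn, st.x_cn)
        np.testing.assert_allclose(g_kn, st.x_kn)

    @pytest.mark.parametrize("seed", range(8))
    def test_match_finite_differences(self, seed, tiny_stimulus, tiny_templates,
                                      generic_params):
        st = random_state(np.random.default_rng(100 + seed), generic_params)
        analytic = pe_gradients(st, tiny_stimulus, tiny_templates, generic_params)
        numeric = finite_difference(
            lambda s: pe_total_energy(s, tiny_stimulus, tiny_templates, generic_params),
            st, generic_params)
        for ga, gn in zip(analytic, numeric):
            assert np.linalg.norm(ga - gn) <= 1e-6 * max(np.linalg.norm(gn), 1e-12)

    def test_best_predictor_rises(self, tiny_stimulus, tiny_templates):
        # when the focus holds template 0, unit 0's prediction should be
        # pushed up and unit 1's down (the inhibitory-feedback sign at work)
        p = ModelParams(a_sn=0.0, a_kn=0.0, b_cn=0.0, b_kn=1.0)
        w = tiny_templates.weights[0]
        y_kn = np.array([0.3, 0.3])
        st = NetworkState(x_sn=sigmoid_inverse(np.full((3, 3), 0.1), p),
                          y_sn=np.full((3, 3), 0.1), x_cn=w.astype(float),
                          x_kn=sigmoid_inverse(y_kn, p), y_kn=y_kn)
        g_kn = pe_gradients(st, tiny_stimulus, tiny_templates, p)[2]
        drive = -(g_kn - st.x_kn)   # b-weighted error term alone
        assert drive[0] > drive[1]


class TestRunPe:
    def test_noiseless_repeats_are_identical(self, tiny_stimulus, tiny_templates):
        p = ModelParams(noise_sd=0.0, max_iters=40, rt_threshold=0.56)
        a = run_pe(tiny_stimulus, tiny_templates, p, seed=1)
        b = run_pe(tiny_stimulus, tiny_templates, p, seed=50)
        np.testing.assert_array_equal(a.kn_trajectory, b.kn_trajectory)

    def test_error_reduction_during_inference(self):
        ts = reference_templates("pe")
        scenes = reference_scenes(ts)
        p = reference_params("pe").replace(noise_sd=0.0, max_iters=3000)
        model = PEModel(scenes["plus"], ts, p)
        r = run_pe(scenes["plus"], ts, p, seed=0, stop_at_threshold=False)
        eps0 = model.errors(model.initial_state())[0]
        eps1 = model.errors(r.final_state)[0]
        assert np.linalg.norm(eps1) < np.linalg.norm(eps0)

    def test_leading_template_agrees_with_em_winner(self):
        """On noiseless single-object scenes both schemes prefer the same
        template (the prediction-error variant's leading unit vs the
        excitatory variant's threshold winner)."""
        em_ts = reference_templates("em")
        pe_ts = reference_templates("pe")
        em_p = reference_params("em").replace(noise_sd=0.0)
        pe_p = reference_params("pe").replace(noise_sd=0.0, max_iters=20000)
        for name in ("plus", "two"):
            em_r = run_em(reference_scenes(em_ts)[name], em_ts, em_p, seed=0)
            pe_r = run_pe(reference_scenes(pe_ts)[name], pe_ts, pe_p, seed=0,
                          stop_at_threshold=False)
            leader = pe_ts.labels[int(np.argmax(pe_r.final_state.y_kn))]
            assert em_r.winner == leader == name
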