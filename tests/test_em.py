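import numpy as np
import pytest

from saim import (ModelParams, TemplateSet, compose_scene, em_gradients,
                  em_total_energy, log_density_components, reference_params,
                  reference_templates, run_em, sigma_pi_input, template_match)
from saim.em import EMModel, selection_drive
from saim.stimuli import reference_scenes

from conftest import finite_difference, random_state


class TestTemplateMatch:
    def test_orthogonal_binary_templates(self):
        a = np.zeros((3, 3)); a[0] = 1.0
        b = np.zeros((3, 3)); b[2] = 1.0
        ts = TemplateSet((a, b), ("top", "bottom"), normalize="none")
        np.testing.assert_allclose(template_match(a, ts), [3.0, 0.0])

    def test_zero_content_matches_nothing(self, tiny_templates):
        assert not template_match(np.zeros((3, 3)), tiny_templates).any()

    def test_bilinearity_on_mixture(self, tiny_templates):
        w1, w2 = tiny_templates.templates
        got = template_match(0.5 * (w1 + w2), tiny_templates)
        dot = float((w1 * w2).sum())
        expected = [0.5 * ((w1 ** 2).sum() + dot), 0.5 * ((w2 ** 2).sum() + dot)]
        np.testing.assert_allclose(got, expected)

    def test_shape_mismatch_rejected(self, tiny_templates):
        with pytest.raises(ValueError):
            template_match(np.zeros((4, 4)), tiny_templates)


def naive_sigma_pi(y_sn, image, m):
    """Quadruple-loop reference for the Sigma-pi gated input."""
    p = y_sn.shape[0]
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            for r in range(p):
                for c in range(p):
                    out[a, b] += y_sn[r, c] * image[r + a, c + b]
    return out


class TestSigmaPi:
    def test_zero_selection_gives_zero(self, tiny_stimulus):
        assert not sigma_pi_input(np.zeros((3, 3)), tiny_stimulus, 3).any()

    def test_one_hot_selection_extracts_patch(self, tiny_stimulus):
        y = np.zeros((3, 3)); y[1, 1] = 1.0
        got = sigma_pi_input(y, tiny_stimulus, 3)
        np.testing.assert_array_equal(got, tiny_stimulus.image[1:4, 1:4])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_loop(self, seed, tiny_stimulus):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 1, (3, 3))
        got = sigma_pi_input(y, tiny_stimulus, 3)
        np.testing.assert_allclose(got, naive_sigma_pi(y, tiny_stimulus.image, 3))

    def test_uniform_selection(self, tiny_stimulus):
        y = np.full((3, 3), 0.2)
        np.testing.assert_allclose(sigma_pi_input(y, tiny_stimulus, 3),
                                   naive_sigma_pi(y, tiny_stimulus.image, 3))

    def test_selection_drive_is_adjoint_of_gating(self, tiny_stimulus):
        # <D(x), y> == <x, I(y)>: the correlation drive is the transpose map
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, (3, 3))
        x = rng.normal(0, 1, (3, 3))
        lhs = float(np.sum(selection_drive(x, tiny_stimulus) * y))
        rhs = float(np.sum(x * sigma_pi_input(y, tiny_stimulus, 3)))
        assert lhs == pytest.approx(rhs)


class TestGradients:
    def test_zero_state_zero_weights(self, tiny_stimulus, tiny_templates):
        p = ModelParams(a_sn=0.0, a_kn=0.0, b_cn=0.0, b_kn=0.0)
        st = random_state(np.random.default_rng(0), p)
        st.x_sn[:] = 0; st.y_sn[:] = 0.5; st.x_cn[:] = 0; st.x_kn[:] = 0; st.y_kn[:] = 0.5
        g_sn, g_cn, g_kn = em_gradients(st, tiny_stimulus, tiny_templates, p)
        assert not g_sn.any() and not g_cn.any() and not g_kn.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_match_finite_differences(self, seed, tiny_stimulus, tiny_templates,
                                      generic_params):
        st = random_state(np.random.default_rng(seed), generic_params)
        analytic = em_gradients(st, tiny_stimulus, tiny_templates, generic_params)
        numeric = finite_difference(
            lambda s: em_total_energy(s, tiny_stimulus, tiny_templates, generic_params),
            st, generic_params)
        for ga, gn in zip(analytic, numeric):
            assert np.linalg.norm(ga - gn) <= 1e-6 * max(np.linalg.norm(gn), 1e-12)

    def test_winner_gradient_vanishes_at_convergence(self):
        ts = reference_templates("em")
        scenes = reference_scenes(ts)
        p = reference_params("em").replace(noise_sd=0.0, max_iters=4000)
        r = run_em(scenes["plus"], ts, p, seed=0, stop_at_threshold=False)
        model = EMModel(scenes["plus"], ts, p)
        g_kn = model.gradients(r.final_state)[2]
        winner = int(np.argmax(r.final_state.y_kn))
        assert abs(g_kn[winner]) < 1e-3


class TestRunEm:
    def test_noiseless_repeats_are_identical(self, tiny_stimulus, tiny_templates):
        p = ModelParams(noise_sd=0.0, max_iters=50, rt_threshold=0.9)
        a = run_em(tiny_stimulus, tiny_templates, p, seed=1)
        b = run_em(tiny_stimulus, tiny_templates, p, seed=99)
        np.testing.assert_array_equal(a.kn_trajectory, b.kn_trajectory)

    def test_seeded_noise_is_reproducible(self, tiny_stimulus, tiny_templates):
        p = ModelParams(noise_sd=0.05, max_iters=50)
        a = run_em(tiny_stimulus, tiny_templates, p, seed=7)
        b = run_em(tiny_stimulus, tiny_templates, p, seed=7)
        np.testing.assert_array_equal(a.kn_trajectory, b.kn_trajectory)
        c = run_em(tiny_stimulus, tiny_templates, p, seed=8)
        assert not np.array_equal(a.kn_trajectory, c.kn_trajectory)

    def test_single_object_scenes_identified_correctly(self):
        ts = reference_templates("em")
        scenes = reference_scenes(ts)
        p = reference_params("em").replace(noise_sd=0.0)
        for name, expected in (("plus", "plus"), ("two", "two")):
            r = run_em(scenes[name], ts, p, seed=0)
            assert not r.timed_out and r.winner == expected and not r.error

    def test_timeout_flags_and_undefined_rt(self, tiny_stimulus, tiny_templates):
        p = ModelParams(noise_sd=0.0, max_iters=3, rt_threshold=0.999)
        r = run_em(tiny_stimulus, tiny_templates, p, seed=0)
        assert r.timed_out and r.rt is None and r.winner is None and not r.error


class TestGenerativeReading:
    def test_components_negate_energies_and_sum(self, tiny_stimulus, tiny_templates,
                                                generic_params):
        st = random_state(np.random.default_rng(11), generic_params)
        comps = log_density_components(st, tiny_stimulus, tiny_templates, generic_params)
        model = EMModel(tiny_stimulus, tiny_templates, generic_params)
        energies = model.energy_components(st)
        assert comps["log_likelihood"] == pytest.approx(-energies["contents"])
        assert comps["sn_prior"] == pytest.approx(-energies["selection"])
        assert comps["cn_empirical_prior"] + comps["kn_prior"] == pytest.approx(
            -energies["knowledge"])
        total = sum(comps.values())
        assert total == pytest.approx(-(energies["selection"] + energies["contents"]
                                        + energies["knowledge"]))

    def test_sn_prior_zero_at_unit_sum(self, tiny_stimulus, tiny_templates,
                                       generic_params):
        st = random_state(np.random.default_rng(12), generic_params)
        st.y_sn[:] = 1.0 / st.y_sn.size   # rates summing exactly to one
        comps = log_density_components(st, tiny_stimulus, tiny_templates, generic_params)
        assert comps["sn_prior"] == pytest.approx(0.0)


def test_translation_invariance_noiseless():
    """Moving the object moves the selection peak but not the decision."""
    ts = reference_templates("em")
    p = reference_params("em").replace(noise_sd=0.0)
    outcomes = []
    for pos in ((6, 6), (6, 8), (8, 7)):
        scene = compose_scene(ts, [("plus", *pos)], 21, expected_winner="plus")
        r = run_em(scene, ts, p, seed=0)
        peak = np.unravel_index(np.argmax(r.final_state.y_sn), r.final_state.y_sn.shape)
        outcomes.append((r.rt, r.winner, tuple(int(i) for i in peak), pos))
    rts = {o[0] for o in outcomes}
    winners = {o[1] for o in outcomes}
    assert rts == {outcomes[0][0]} and winners == {"plus"}
    for rt, winner, peak, pos in outcomes:
        assert peak == pos
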