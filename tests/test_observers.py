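"""Observer contract: decision rules, criteria, adapters, determinism."""

import numpy as np
import pytest

from classimage import (ObserverSpec, classify, classify_batch,
                        classify_from_parameters, external_adapter,
                        sample_parameters, superimpose, synthesize_noise,
                        trials_to_frame)


def make_linear(tiny_basis, tiny_template, axis=None, **kw):
    if axis is None:
        axis = tiny_basis.component_image(0)
    return ObserverSpec(kind="linear_template", axis=axis,
                        template=tiny_template, **kw)


def build_stimuli(tiny_basis, tiny_template, params):
    return [superimpose(tiny_template, synthesize_noise(tiny_basis, v),
                        amplitude_bound=tiny_basis.amplitude_bound)
            for v in np.atleast_2d(params)]


class TestLinearObserver:
    def test_tie_at_threshold_goes_male(self, tiny_basis, tiny_template):
        obs = make_linear(tiny_basis, tiny_template, sigma=0.0, theta=0.0)
        rec = classify(obs, tiny_template)           # zero noise -> v = 0
        assert rec.decision_var == 0.0
        assert rec.label == "male"

    def test_single_component_noise_matches_dot_product_oracle(
            self, tiny_basis, tiny_template):
        # axis = component 0; noise amplitude +1 on that component only
        obs = make_linear(tiny_basis, tiny_template)
        v = np.zeros(30)
        v[0] = 1.0
        stim = build_stimuli(tiny_basis, tiny_template, v)[0]
        rec = classify(obs, stim)
        comp = tiny_basis.component_image(0)
        expected_v = float(np.sum((stim - tiny_template) * comp))
        assert np.isclose(rec.decision_var, expected_v)
        assert expected_v > 0 and rec.label == "female"

    def test_label_sign_follows_axis_inner_product(self, tiny_basis,
                                                   tiny_template, rng):
        axis = tiny_basis.component_image(3) - tiny_basis.component_image(17)
        obs = make_linear(tiny_basis, tiny_template, axis=axis)
        params = sample_parameters(tiny_basis, 40, seed=8)
        for i, stim in enumerate(build_stimuli(tiny_basis, tiny_template, params)):
            rec = classify(obs, stim, trial_index=i)
            noise = synthesize_noise(tiny_basis, params[i])
            dot = float(np.sum(noise * axis))       # brute-force ground truth
            assert rec.label == ("female" if dot > 0 else "male")

    def test_pixel_and_parameter_paths_agree(self, tiny_basis, tiny_template):
        obs = make_linear(tiny_basis, tiny_template,
                          axis=tiny_basis.component_image(5))
        params = sample_parameters(tiny_basis, 30, seed=2)
        stims = build_stimuli(tiny_basis, tiny_template, params)
        recs = trials_to_frame(classify_batch(obs, stims))
        fast = classify_from_parameters(obs, tiny_basis, params)
        assert list(recs["label"]) == list(fast["label"])
        assert np.allclose(recs["decision_var"], fast["decision_var"])


class TestRandomObserver:
    def test_fraction_female_near_half(self, tiny_basis):
        obs = ObserverSpec(kind="random", seed=4)
        params = sample_parameters(tiny_basis, 10000, seed=4)
        labels = classify_from_parameters(obs, tiny_basis, params)["label"]
        frac = (labels == "female").mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_reproducible_per_seed_and_trial(self, tiny_template):
        obs = ObserverSpec(kind="random", seed=9)
        a = [classify(obs, tiny_template, trial_index=i).label for i in range(20)]
        b = [classify(obs, tiny_template, trial_index=i).label for i in range(20)]
        assert a == b


class TestCriteria:
    def test_mean_activation_equals_fixed_threshold_at_batch_mean(
            self, tiny_basis, tiny_template):
        axis = tiny_basis.component_image(2)
        params = sample_parameters(tiny_basis, 200, seed=6)
        stims = build_stimuli(tiny_basis, tiny_template, params)
        obs_ma = make_linear(tiny_basis, tiny_template, axis=axis,
                             criterion="mean_activation")
        recs_ma = classify_batch(obs_ma, stims)
        vs = np.array([r.decision_var for r in recs_ma])
        obs_ft = make_linear(tiny_basis, tiny_template, axis=axis,
                             theta=float(np.mean(vs)))
        recs_ft = classify_batch(obs_ft, stims)
        assert [r.label for r in recs_ma] == [r.label for r in recs_ft]

    def test_constant_bias_yields_balanced_labels(self, tiny_basis, tiny_template):
        # scorer with a huge constant offset on the female unit
        def scorer(img):
            return (1000.0 + img[0, 0], 0.0)

        obs = external_adapter(scorer, criterion="mean_activation")
        params = sample_parameters(tiny_basis, 400, seed=13)
        stims = build_stimuli(tiny_basis, tiny_template, params)
        labels = [r.label for r in classify_batch(obs, stims)]
        frac = np.mean([l == "female" for l in labels])
        assert 0.35 < frac < 0.65

    def test_batch_of_one_under_mean_activation_is_male(self, tiny_basis,
                                                        tiny_template):
        obs = make_linear(tiny_basis, tiny_template, criterion="mean_activation")
        [rec] = classify_batch(obs, [tiny_template])
        assert rec.label == "male"       # v equals its own mean; tie rule

    def test_single_trial_mean_activation_rejected(self, tiny_basis, tiny_template):
        obs = make_linear(tiny_basis, tiny_template, criterion="mean_activation")
        with pytest.raises(ValueError, match="classify_batch"):
            classify(obs, tiny_template)

    def test_empty_batch_rejected(self, tiny_basis, tiny_template):
        obs = make_linear(tiny_basis, tiny_template)
        with pytest.raises(ValueError):
            classify_batch(obs, [])


class TestExternalAdapter:
    def test_constant_stub_maps_to_one_label(self, tiny_template):
        obs = external_adapter(lambda img: (1.0, 0.0))
        recs = classify_batch(obs, [tiny_template] * 5)
        assert all(r.label == "female" for r in recs)
        assert recs[0].extras == {"score_0": 1.0, "score_1": 0.0}

    def test_brightness_stub_flips_with_image_mean(self):
        obs = external_adapter(lambda img: (img.mean(), 1 - img.mean()))
        bright = np.full((4, 4), 0.9)
        dark = np.full((4, 4), 0.1)
        assert classify(obs, bright).label == "female"
        assert classify(obs, dark).label == "male"

    def test_male_unit_higher_means_male(self):
        # the fixed-threshold contract for two-unit classifier scores
        obs = external_adapter(lambda img: (0.4, 0.6))
        assert classify(obs, np.zeros((4, 4))).label == "male"
        obs2 = external_adapter(lambda img: (0.6, 0.4))
        assert classify(obs2, np.zeros((4, 4))).label == "female"

    def test_malformed_scores_reported_with_payload(self):
        obs = external_adapter(lambda img: "oops")
        with pytest.raises(ValueError, match="oops"):
            classify(obs, np.zeros((4, 4)))

    def test_label_map_reorders_classes(self, tiny_template):
        obs = external_adapter(lambda img: (1.0, 0.0),
                               label_map={0: "male", 1: "female"})
        assert classify(obs, tiny_template).label == "male"


class TestDeterminismAndNoise:
    def test_internal_noise_stream_reproducible(self, tiny_basis, tiny_template):
        obs = make_linear(tiny_basis, tiny_template, sigma=0.5, seed=21)
        a = [classify(obs, tiny_template, trial_index=i).decision_var
             for i in range(10)]
        b = [classify(obs, tiny_template, trial_index=i).decision_var
             for i in range(10)]
        assert a == b
        assert len(set(a)) > 1       # noise actually varies across trials

    def test_confidence_grades_collapse_to_binary_label(self, tiny_basis,
                                                        tiny_template):
        obs = make_linear(tiny_basis, tiny_template,
                          axis=tiny_basis.component_image(1))
        params = sample_parameters(tiny_basis, 50, seed=30)
        stims = build_stimuli(tiny_basis, tiny_template, params)
        for rec in classify_batch(obs, stims):
            assert rec.response4.endswith(rec.label)
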