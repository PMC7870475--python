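"""Classification-image estimation, scale decomposition, similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from classimage import (ObserverSpec, ci_by_scale, ci_similarity, compute_ci,
                        make_template, normalize_ci_for_display,
                        sample_parameters, classify_from_parameters,
                        simulate_linear_observer_run, make_axis)


def frame(labels, pv_ids=None):
    pv = pv_ids if pv_ids is not None else list(range(len(labels)))
    return pd.DataFrame({"label": labels, "pv_id": pv})


class TestComputeCI:
    def test_hand_mean_difference(self, tiny_basis):
        params = np.zeros((2, 30))
        params[0, 1] = 1.0       # female trial: +e1
        params[1, 1] = -1.0      # male trial: -e1
        ci = compute_ci(frame(["female", "male"]), params, tiny_basis)
        expected = np.zeros(30)
        expected[1] = 2.0
        assert np.array_equal(ci.param_ci, expected)
        assert ci.n_female == 1 and ci.n_male == 1

    def test_label_swap_negates_ci(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (20, 30))
        labels = ["female"] * 12 + ["male"] * 8
        swapped = ["male" if l == "female" else "female" for l in labels]
        a = compute_ci(frame(labels), params, tiny_basis)
        b = compute_ci(frame(swapped), params, tiny_basis)
        assert np.allclose(a.param_ci, -b.param_ci)
        assert np.allclose(a.pixel_ci, -b.pixel_ci)

    def test_null_labels_give_near_zero_ci(self, tiny_basis):
        n = 5000
        params = sample_parameters(tiny_basis, n, seed=42)
        obs = ObserverSpec(kind="random", seed=42)
        trials = classify_from_parameters(obs, tiny_basis, params)
        ci = compute_ci(trials, params, tiny_basis)
        nf, nm = ci.n_female, ci.n_male
        se = np.sqrt((1.0 / 3.0) * (1.0 / nf + 1.0 / nm))
        assert np.all(np.abs(ci.param_ci) < 4 * se)

    def test_pixel_ci_is_synthesis_of_param_ci(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        ci = compute_ci(frame(["female"] * 5 + ["male"] * 5), params, tiny_basis)
        assert np.allclose(ci.pixel_ci, tiny_basis.synthesize(ci.param_ci))

    def test_concatenation_consistency(self, tiny_basis, rng):
        pa = rng.uniform(-1, 1, (8, 30))
        pb = rng.uniform(-1, 1, (6, 30))
        la, lb = ["female"] * 5 + ["male"] * 3, ["female"] * 2 + ["male"] * 4
        both = compute_ci(frame(la + lb), np.vstack([pa, pb]), tiny_basis)
        fem = np.vstack([pa[:5], pb[:2]]).mean(axis=0)
        mal = np.vstack([pa[5:], pb[2:]]).mean(axis=0)
        assert np.allclose(both.param_ci, fem - mal)

    def test_single_class_rejected_naming_missing_class(self, tiny_basis):
        params = np.zeros((3, 30))
        with pytest.raises(ValueError, match="male"):
            compute_ci(frame(["female"] * 3), params, tiny_basis)


class TestScaleDecomposition:
    def test_per_scale_images_sum_to_pixel_ci(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        ci = compute_ci(frame(["female"] * 4 + ["male"] * 6), params, tiny_basis)
        total = sum(ci_by_scale(ci, s) for s in tiny_basis.config.scales)
        assert np.allclose(total, ci.pixel_ci)

    def test_single_parameter_ci_reduces_to_weighted_component(self, tiny_basis):
        k = tiny_basis.scale_indices(4)[2]
        params = np.zeros((2, 30))
        params[0, k] = 1.0
        params[1, k] = -1.0
        ci = compute_ci(frame(["female", "male"]), params, tiny_basis)
        assert np.allclose(ci_by_scale(ci, 4),
                           2.0 * tiny_basis.component_image(k))

    def test_axis_confined_to_coarse_scale_leaves_finest_scale_null(
            self, small_basis):
        axis = make_axis(small_basis, components=small_basis.scale_indices(2)[:3],
                         coefficients=[1.0, -1.0, 1.0])
        template = make_template(small_basis.image_size, style="flat")
        params, trials = simulate_linear_observer_run(
            small_basis, axis, template, 4000, seed=5)
        ci = compute_ci(trials, params, small_basis)
        nf, nm = ci.n_female, ci.n_male
        se = np.sqrt((1.0 / 3.0) * (1.0 / nf + 1.0 / nm))
        finest = ci.param_ci[small_basis.scale_indices(32)]
        assert np.all(np.abs(finest) < 4 * se)


class TestSimilarity:
    def test_self_similarity_is_one(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        ci = compute_ci(frame(["female"] * 5 + ["male"] * 5), params, tiny_basis)
        rep = ci_similarity(ci, ci, per_scale=True)
        assert np.isclose(rep["overall"], 1.0)
        assert all(np.isclose(r, 1.0) for r in rep["per_scale"].values())

    def test_negated_ci_gives_minus_one(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        labels = ["female"] * 5 + ["male"] * 5
        swapped = ["male"] * 5 + ["female"] * 5
        a = compute_ci(frame(labels), params, tiny_basis)
        b = compute_ci(frame(swapped), params, tiny_basis)
        assert np.isclose(ci_similarity(a, b)["overall"], -1.0)

    def test_parameter_space_option(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        ci = compute_ci(frame(["female"] * 5 + ["male"] * 5), params, tiny_basis)
        assert np.isclose(ci_similarity(ci, ci, space="parameter")["overall"], 1.0)

    def test_independent_random_observers_correlate_weakly(self, tiny_basis):
        params = sample_parameters(tiny_basis, 3000, seed=1)
        cis = []
        for seed in (10, 20):
            obs = ObserverSpec(kind="random", seed=seed)
            trials = classify_from_parameters(obs, tiny_basis, params)
            cis.append(compute_ci(trials, params, tiny_basis))
        assert abs(ci_similarity(cis[0], cis[1])["overall"]) < 0.35

    def test_zero_variance_ci_reported_as_nan(self, tiny_basis):
        params = np.zeros((4, 30))
        ci = compute_ci(frame(["female"] * 2 + ["male"] * 2), params, tiny_basis)
        assert np.isnan(ci_similarity(ci, ci)["overall"])

    def test_mismatched_bases_rejected(self, tiny_basis, small_basis, rng):
        pa = rng.uniform(-1, 1, (4, tiny_basis.n_params))
        pb = rng.uniform(-1, 1, (4, small_basis.n_params))
        a = compute_ci(frame(["female"] * 2 + ["male"] * 2), pa, tiny_basis)
        b = compute_ci(frame(["female"] * 2 + ["male"] * 2), pb, small_basis)
        with pytest.raises(ValueError):
            ci_similarity(a, b)


class TestDisplayNormalization:
    def test_range_contract(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        ci = compute_ci(frame(["female"] * 5 + ["male"] * 5), params, tiny_basis)
        img = normalize_ci_for_display(ci)
        assert img.dtype == np.uint8
        assert img.min() == 0 and img.max() == 255

    def test_preserves_pixel_ranking(self, tiny_basis, rng):
        params = rng.uniform(-1, 1, (10, 30))
        ci = compute_ci(frame(["female"] * 5 + ["male"] * 5), params, tiny_basis)
        unit = normalize_ci_for_display(ci, as_uint8=False)
        order_raw = np.argsort(ci.pixel_ci.ravel())
        order_norm = np.argsort(unit.ravel())
        assert np.array_equal(order_raw, order_norm)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-5.0, 5.0))
    def test_affine_invariance(self, tiny_basis, a, b):
        r = np.random.default_rng(0)
        pix = r.normal(size=(16, 16))
        assert np.allclose(normalize_ci_for_display(pix, as_uint8=False),
                           normalize_ci_for_display(a * pix + b, as_uint8=False),
                           atol=1e-9)

    def test_constant_ci_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_ci_for_display(np.full((4, 4), 2.0))
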