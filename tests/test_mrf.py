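import itertools

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from organotrack.config import MRFConfig
from organotrack.mrf import (LABELS, MixtureModel3, MRFModel, alpha_expansion,
                             build_energy, fit_mixture3, segment_stack,
                             unary_quantiles)
from organotrack.synth import generate_mrf_image


def exhaustive_minimum(model):
    h, w = model.shape
    best = np.inf
    for combo in itertools.product(range(3), repeat=h * w):
        e = model.energy(np.array(combo).reshape(h, w))
        best = min(best, e)
    return best


class TestMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(m, 5, 1000) for m in (10, 100, 200)])
        mix = fit_mixture3(vals, seed=0)
        np.testing.assert_allclose(mix.means, [10, 100, 200], atol=2)

    def test_two_value_degenerate_data_no_crash(self):
        vals = np.tile([0.0, 100.0], 500)
        mix = fit_mixture3(vals, seed=1)
        assert np.all(mix.sigmas > 0)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(50, 30, 2000)
        a = fit_mixture3(vals, seed=5)
        b = fit_mixture3(vals, seed=5)
        np.testing.assert_array_equal(a.means, b.means)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture3(np.arange(100), seed=0)

    def test_components_sorted_by_mean(self):
        mix = MixtureModel3(weights=[0.2, 0.5, 0.3], means=[200, 10, 100],
                            sigmas=[5, 5, 5])
        np.testing.assert_array_equal(mix.means, [10, 100, 200])


class TestBuildEnergy:
    def test_hand_computed_2x2_energy(self):
        mix = MixtureModel3(weights=[1 / 3] * 3, means=[0.0, 10.0, 20.0],
                            sigmas=[2.0, 2.0, 2.0])
        img = np.array([[0.0, 10.0], [10.0, 20.0]])
        l0, l1, beta = 0.5, 2.0, 0.01
        model = build_energy(img, mix, l0, l1, beta)
        lab = np.array([[0, 1], [1, 2]])
        # manual arithmetic: unaries + all four 4-neighbor pairs cut
        # (labels 0|1, 1|2 horizontally; 0|1, 1|2 vertically)
        dens = mix.component_density(img)
        expected = sum(-np.log(dens[i, j, lab[i, j]])
                       for i in range(2) for j in range(2))
        for (za, zb) in ((0.0, 10.0), (10.0, 20.0), (0.0, 10.0), (10.0, 20.0)):
            expected += l0 + l1 * np.exp(-0.5 * beta * (za - zb) ** 2)
        assert model.energy(lab) == pytest.approx(expected, rel=1e-12)

    def test_zero_lambdas_decouple(self):
        mix = MixtureModel3([1 / 3] * 3, [0, 100, 200], [5, 5, 5])
        img, _ = generate_mrf_image((8, 8), means=(0, 100, 200),
                                    sigmas=(5, 5, 5), seed=0)
        model = build_energy(img, mix, 0.0, 0.0, 0.05)
        assert np.all(model.wh == 0) and np.all(model.wv == 0)

    def test_beta_zero_is_potts(self):
        mix = MixtureModel3([1 / 3] * 3, [0, 100, 200], [5, 5, 5])
        img, _ = generate_mrf_image((8, 8), seed=1)
        model = build_energy(img, mix, 0.5, 2.0, 0.0)
        np.testing.assert_allclose(model.wh, 2.5)
        np.testing.assert_allclose(model.wv, 2.5)

    def test_negative_lambda_rejected(self):
        mix = MixtureModel3([1 / 3] * 3, [0, 100, 200], [5, 5, 5])
        with pytest.raises(ValueError):
            build_energy(np.zeros((4, 4)), mix, -0.1, 1.0, 0.05)


class TestAlphaExpansion:
    def test_ml_labeling_in_decoupled_limit(self, rng):
        unary = rng.uniform(0, 5, (5, 5, 3))
        model = MRFModel(unary, np.zeros((5, 4)), np.zeros((4, 5)), 0, 0, 0)
        lab, _ = alpha_expansion(model,
                                 init_labeling=np.zeros((5, 5), dtype=int))
        np.testing.assert_array_equal(lab, np.argmin(unary, axis=2))

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_minimum_on_3x3(self, seed):
        rng = np.random.default_rng(seed)
        unary = rng.uniform(0, 5, (3, 3, 3))
        wh = rng.uniform(0, 2, (3, 2))
        wv = rng.uniform(0, 2, (2, 3))
        model = MRFModel(unary, wh, wv, 0, 0, 0)
        _, e = alpha_expansion(model)
        assert e == pytest.approx(exhaustive_minimum(model), rel=1e-9)

    def test_phantom_accuracy_sigma15(self):
        img, labels = generate_mrf_image((96, 96), means=(10, 100, 200),
                                         sigmas=(15, 15, 15), seed=3)
        mix = fit_mixture3(img.ravel(), seed=0)
        model = build_energy(img, mix, 0.5, 2.0, 0.05)
        lab, _ = alpha_expansion(model)
        assert (lab == labels).mean() >= 0.98

    def test_negative_pairwise_rejected(self):
        model = MRFModel(np.zeros((2, 2, 3)), np.full((2, 1), -1.0),
                         np.zeros((1, 2)), 0, 0, 0)
        with pytest.raises(ValueError, match="metric"):
            alpha_expansion(model)


def _textured_labels(offset):
    lm = np.zeros((160, 160), dtype=int)
    rr, cc = draw_disk((80 + offset, 80 + offset), 55, shape=lm.shape)
    lm[rr, cc] = 1
    rr, cc = draw_disk((80 + offset, 80 + offset), 34, shape=lm.shape)
    lm[rr, cc] = 2
    return lm


def _textured_image(lm, seed):
    img, _ = generate_mrf_image(lm.shape, label_map=lm, means=(30, 100, 200),
                                sigmas=(2, 8, 25), seed=seed)
    return img


class TestSegmentStack:
    def test_disjoint_channels_no_both_pixels(self):
        la, lb = _textured_labels(-42), _textured_labels(42)
        labelings, overlay = segment_stack(
            {"tumor": _textured_image(la, 5), "caf": _textured_image(lb, 6)},
            ["tumor", "caf"], seed=1)
        true_overlap = ((la == 2) & (lb == 2)).sum()
        assert true_overlap == 0
        assert (overlay == 3).sum() == 0

    def test_overlap_recovered_within_ten_percent(self):
        la, lb = _textured_labels(-12), _textured_labels(12)
        labelings, overlay = segment_stack(
            {"tumor": _textured_image(la, 7), "caf": _textured_image(lb, 8)},
            ["tumor", "caf"], seed=1)
        both = (overlay == 3).sum()
        true_overlap = ((la == 2) & (lb == 2)).sum()
        assert both == pytest.approx(true_overlap, rel=0.1)

    def test_determinism(self):
        la = _textured_labels(0)
        img = _textured_image(la, 9)
        l1, o1 = segment_stack({"c": img}, ["c"], seed=3)
        l2, o2 = segment_stack({"c": img}, ["c"], seed=3)
        np.testing.assert_array_equal(l1["c"], l2["c"])

    def test_zstack_max_projected(self):
        la = _textured_labels(0)
        img = _textured_image(la, 10)
        stack3d = np.stack([img * 0.5, img, img * 0.3])
        l3, _ = segment_stack({"c": stack3d}, ["c"], seed=3)
        assert l3["c"].shape == la.shape

    def test_missing_channel_named(self):
        with pytest.raises(KeyError, match="caf"):
            segment_stack({"tumor": np.zeros((32, 32))}, ["caf"], seed=0)


def test_unary_quantiles_reports_all_labels():
    mix = MixtureModel3([1 / 3] * 3, [0, 100, 200], [5, 5, 5])
    img, _ = generate_mrf_image((16, 16), seed=2)
    model = build_energy(img, mix)
    q = unary_quantiles(model)
    assert set(q) == set(LABELS)
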