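"""Attribution methods: finite-difference oracle for Grad-CAM, fusion-rule
properties for Multi-Layer Grad-CAM, LIME surrogate sanity, and the
modality-contribution metric."""

import numpy as np
import pytest

from cardiofuse import (BimodalSample, Recording, fuse_layer_maps, grad_cam,
                        lime_heatmaps, lime_timeseries, modality_contribution,
                        multilayer_grad_cam, sample_contributions,
                        compare_contributions)
from cardiofuse import _nn as nn
from cardiofuse.explain import Heatmap, _abs_pearson
from cardiofuse.models import BranchNet


def _sample(ecg, pcg, label="abnormal"):
    return BimodalSample(
        ecg=Recording(ecg, 500.0, "ECG", "e0", "p0"),
        pcg=Recording(pcg, 1000.0, "PCG", "p0r", "p0"),
        label=label, patient_id="p0", sample_id="s0")


def _linear_toy_branch(kernel=3, length=64, seed=0):
    """1-channel conv -> global average pool -> dense: fully linear, so the
    logit's gradient w.r.t. the conv activation is available in closed form
    and by finite differences."""
    rng = np.random.default_rng(seed)
    conv = nn.Conv1d(1, 1, kernel, rng, dtype=np.float64)
    head = nn.Sequential([nn.Dense(1, 1, rng, dtype=np.float64)])
    return BranchNet([nn.Sequential([conv])], head, embedding_dim=1), conv


class TestGradCam:
    def test_map_matches_input_length_and_nonnegative(self, trained_fusion,
                                                      tiny_split):
        _, _, te = tiny_split
        s = te[0]
        for branch, sig in (("ecg", s.ecg), ("pcg", s.pcg)):
            hm = grad_cam(trained_fusion.net_, s, branch)
            assert hm.values.size == sig.samples.size
            assert (hm.values >= 0).all()

    def test_matches_finite_difference_saliency_on_linear_toy(self):
        net, conv = _linear_toy_branch()
        rng = np.random.default_rng(1)
        x = rng.standard_normal(64)
        sample = _sample(x, np.zeros(128))
        hm = grad_cam(net, sample, "ecg")

        # oracle: activation map from the conv, gradient of the logit w.r.t.
        # each activation entry by central finite differences through the
        # head (global average pool -> dense)
        act = conv.forward(x[None, :, None])[0, :, 0]
        W, b = net.head.layers[0].params["W"], net.head.layers[0].params["b"]

        def head_fn(a):
            return float(a.mean() * W[0, 0] + b[0])

        h = 1e-3
        grads = np.empty_like(act)
        for i in range(act.size):
            up, down = act.copy(), act.copy()
            up[i] += h
            down[i] -= h
            grads[i] = (head_fn(up) - head_fn(down)) / (2 * h)
        expected = np.maximum(grads.mean() * act, 0.0)
        np.testing.assert_allclose(hm.values, expected, atol=1e-4)

    def test_branch_without_convs_rejected(self):
        rng = np.random.default_rng(0)
        net = BranchNet([], nn.Sequential([nn.Dense(1, 1, rng)]), 1)
        with pytest.raises(ValueError):
            grad_cam(net, _sample(np.zeros(8), np.zeros(16)), "ecg")


class TestMultiLayerFusion:
    def test_identical_maps_fuse_to_themselves(self):
        rng = np.random.default_rng(2)
        m = np.abs(rng.standard_normal(100))
        ref = np.abs(rng.standard_normal(100))
        fused, w = fuse_layer_maps([m, m.copy(), m.copy()], ref)
        np.testing.assert_allclose(fused, m, atol=1e-12)
        assert w.weights.sum() == pytest.approx(1.0)

    def test_constant_map_gets_zero_weight(self):
        rng = np.random.default_rng(3)
        ref = np.abs(rng.standard_normal(100))
        live = np.abs(rng.standard_normal(100))
        const = np.full(100, 3.0)
        fused, w = fuse_layer_maps([live, const], ref)
        assert w.weights[1] == 0.0
        assert w.weights.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(fused, live)

    def test_all_constant_maps_flagged_degenerate(self):
        fused, w = fuse_layer_maps([np.ones(10), np.full(10, 2.0)], np.ones(10))
        assert w.degenerate

    def test_affine_function_of_reference_has_unit_correlation(self):
        rng = np.random.default_rng(4)
        ref = np.abs(rng.standard_normal(200))
        assert _abs_pearson(3.0 * ref + 0.5, ref) == pytest.approx(1.0)

    def test_on_trained_model_weights_convex_and_map_aligned(
            self, trained_fusion, tiny_split):
        _, _, te = tiny_split
        hm, w = multilayer_grad_cam(trained_fusion.net_, te[0], "ecg")
        assert hm.values.size == te[0].ecg.samples.size
        assert (hm.values >= 0).all()
        assert w.weights.sum() == pytest.approx(1.0)
        assert (w.weights >= 0).all()

    def test_requires_three_conv_layers(self):
        net, _ = _linear_toy_branch()
        with pytest.raises(ValueError):
            multilayer_grad_cam(net, _sample(np.zeros(64), np.zeros(128)), "ecg")


class _SegmentReaderModel:
    """Toy 'model' that reads only ECG segment 3: its probability is the
    mean absolute first difference (roughness) of that segment. The
    mean/SD-matched replacement noise preserves a segment's moments by
    construction, so the toy must read temporal structure — which the
    perturbation does destroy — for its segment to be attributable."""

    frontend = None  # duck-typed as an ECG branch

    def predict_proba(self, X, batch_size=None):
        n_seg = 16
        seg = X[:, 3 * X.shape[1] // n_seg: 4 * X.shape[1] // n_seg]
        return np.clip(np.abs(np.diff(seg, axis=1)).mean(axis=1), 0.0, 1.0)


def _smooth_signal(n, rng):
    t = np.arange(n) / n
    return np.sin(2 * np.pi * 5 * t) + 0.02 * rng.standard_normal(n)


class TestLime:
    def test_noop_perturbation_yields_null_explanation(self, trained_fusion):
        s = _sample(np.zeros(4000), np.zeros(8000))
        expl = lime_timeseries(trained_fusion.net_, s, n_perturbations=100,
                               seed=0)
        # zero-mean zero-variance segments perturb to themselves: the
        # surrogate sees a constant response
        assert np.abs(expl.segment_weights).max() < 1e-6
        orig = trained_fusion.net_.predict_proba(
            (np.zeros((1, 4000), np.float32), np.zeros((1, 8000), np.float32)))[0]
        assert expl.intercept == pytest.approx(orig, abs=1e-6)

    def test_segment_reader_toy_ranks_its_segment_first(self):
        rng = np.random.default_rng(5)
        x = _smooth_signal(1600, rng)
        s = _sample(x, np.zeros(3200))
        expl = lime_timeseries(_SegmentReaderModel(), s, n_perturbations=500,
                               seed=0)
        assert np.argmax(np.abs(expl.segment_weights)) == 3
        assert expl.surrogate_r2 > 0.5

    def test_seed_determinism_and_underdetermined_rejection(self):
        s = _sample(np.random.default_rng(6).standard_normal(1600),
                    np.zeros(3200))
        model = _SegmentReaderModel()
        a = lime_timeseries(model, s, n_perturbations=64, seed=3)
        b = lime_timeseries(model, s, n_perturbations=64, seed=3)
        np.testing.assert_array_equal(a.segment_weights, b.segment_weights)
        with pytest.raises(ValueError):
            lime_timeseries(model, s, n_perturbations=10)

    def test_doubling_perturbations_is_stable(self):
        rng = np.random.default_rng(7)
        x = _smooth_signal(1600, rng)
        s = _sample(x, np.zeros(3200))
        model = _SegmentReaderModel()
        w1 = lime_timeseries(model, s, n_perturbations=250, seed=0).segment_weights
        w2 = lime_timeseries(model, s, n_perturbations=500, seed=0).segment_weights
        rms = np.sqrt(np.mean((w1 - w2) ** 2)) / np.sqrt(np.mean(w2 ** 2))
        assert rms < 0.10

    def test_heatmap_expansion_covers_signals(self):
        s = _sample(np.random.default_rng(8).standard_normal(1600),
                    np.random.default_rng(9).standard_normal(3200))
        expl = lime_timeseries(_SegmentReaderModel(), s, n_perturbations=64,
                               seed=0)
        he, hp = lime_heatmaps(expl, s)
        assert he.values.size == 1600 and hp.values.size == 3200
        assert (he.values >= 0).all() and (hp.values >= 0).all()


class TestModalityContribution:
    def _hm(self, values, modality):
        return Heatmap(values=np.asarray(values, dtype=float), modality=modality)

    def test_constant_maps_printed_case(self):
        mc = modality_contribution(self._hm(np.full(10, 0.5), "ECG"),
                                   self._hm(np.full(20, 1.0), "PCG"),
                                   "gradcam", "abnormal")
        assert (mc.ecg_mean, mc.pcg_mean) == (0.5, 1.0)

    def test_identical_maps_give_equal_means(self):
        v = np.random.default_rng(10).random(50)
        mc = modality_contribution(self._hm(v, "ECG"), self._hm(v, "PCG"),
                                   "gradcam", "normal")
        assert mc.ecg_mean == pytest.approx(mc.pcg_mean)

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b = rng.random(30) * 5, rng.random(60) * 2
            mc = modality_contribution(self._hm(a, "ECG"), self._hm(b, "PCG"),
                                       "lime", "abnormal")
            m = max(a.max(), b.max())
            assert mc.ecg_mean == pytest.approx((a / m).mean())
            assert mc.pcg_mean == pytest.approx((b / m).mean())

    def test_negative_values_rejected_and_zero_degenerate(self):
        with pytest.raises(ValueError):
            modality_contribution(self._hm([-1.0, 0.5], "ECG"),
                                  self._hm([0.1], "PCG"), "gradcam", "normal")
        mc = modality_contribution(self._hm(np.zeros(5), "ECG"),
                                   self._hm(np.zeros(5), "PCG"),
                                   "gradcam", "normal")
        assert mc.degenerate and mc.ecg_mean == mc.pcg_mean == 0.0


class TestCompareContributions:
    def test_equal_contributions_give_p_one(self):
        from cardiofuse.explain import ModalityContribution
        contribs = [ModalityContribution(0.4, 0.4, "abnormal", "gradcam")
                    for _ in range(8)]
        rows = compare_contributions(contribs)
        assert rows[0]["p"] == 1.0
        assert rows[0]["median_ecg"] == rows[0]["median_pcg"]
        assert rows[0]["stars"] == "ns"

    def test_small_class_skipped_with_warning(self):
        from cardiofuse.explain import ModalityContribution
        contribs = [ModalityContribution(0.4, 0.6, "abnormal", "gradcam")
                    for _ in range(3)]
        with pytest.warns(UserWarning):
            assert compare_contributions(contribs) == []

    def test_end_to_end_contributions_on_trained_model(self, trained_fusion,
                                                       tiny_split):
        _, _, te = tiny_split
        contribs = sample_contributions(trained_fusion.net_, te,
                                        methods=("gradcam",),
                                        lime_kwargs=None)
        assert len(contribs) == len(te)
        assert all(0 <= c.ecg_mean <= 1 and 0 <= c.pcg_mean <= 1
                   for c in contribs)


def test_heatmap_export_and_figures(tmp_path, trained_fusion, tiny_split):
    import pandas as pd
    from cardiofuse.explain import (contribution_boxplot, export_heatmap_csv,
                                    plot_heatmap_overlay)

    _, _, te = tiny_split
    s = te[0]
    hm = grad_cam(trained_fusion.net_, s, "ecg")
    csv_path = str(tmp_path / "hm.csv")
    export_heatmap_csv(hm, s.ecg.fs, csv_path)
    df = pd.read_csv(csv_path)
    assert list(df.columns) == ["time", "value"]
    assert len(df) == s.ecg.samples.size
    plot_heatmap_overlay(hm, s.ecg.samples, s.ecg.fs, str(tmp_path / "hm.png"))
    contribs = sample_contributions(trained_fusion.net_, te,
                                    methods=("gradcam",))
    contribution_boxplot(contribs, "gradcam", str(tmp_path / "box.png"))
    assert (tmp_path / "hm.png").exists() and (tmp_path / "box.png").exists()
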