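"""Unit behaviour of the three trainable image modules on the small fixture
cohort: contracts, determinism, degenerate-input guards."""

import numpy as np
import pytest

from ctatrophy import phantom as ph
from ctatrophy.features import fused_channels
from ctatrophy.measure import (
    MeasureConfig,
    fuse_adjacent,
    oracle_measurements,
    predict_measurements,
    train_measurement_model,
)
from ctatrophy.nn import MLP
from ctatrophy.slice_detect import (
    KEY_NAMES,
    SliceDetectConfig,
    SliceDetectorModel,
    detect_key_slices,
    score_slices,
    train_slice_detector,
)
from ctatrophy.sulci import (
    SulciConfig,
    SulciResult,
    predict_sulci,
    sulci_rule_oracle,
    train_sulci_classifier,
)


# --------------------------------------------------------------- slice detect
class TestSliceDetection:
    def test_score_shapes_and_range(self, mini_subjects, mini_bundle):
        bundle, _ = mini_bundle
        scores = score_slices(mini_subjects[0].stacks[32], bundle.detector)
        assert set(scores) == set(KEY_NAMES)
        for vec in scores.values():
            assert vec.shape == (mini_subjects[0].n_slices,)
            assert np.all((vec >= 0) & (vec <= 1))

    def test_detection_equals_per_slice_argmax(self, mini_subjects, mini_bundle):
        bundle, _ = mini_bundle
        s = mini_subjects[1]
        scores = score_slices(s.stacks[32], bundle.detector)
        ks = detect_key_slices(s.stacks[32], bundle.detector)
        picks = {k: int(np.argmax(v)) for k, v in scores.items()}
        if picks["key1"] <= picks["key2"] < picks["key4"]:
            assert ks.as_tuple() == (picks["key1"], picks["key2"], picks["key3"], picks["key4"])

    def test_ordering_invariant_always_holds(self, mini_subjects, mini_bundle):
        bundle, _ = mini_bundle
        for s in mini_subjects:
            ks = detect_key_slices(s.stacks[32], bundle.detector)
            ks.validate(s.n_slices)

    def test_tie_break_toward_inferior_slice(self):
        """Equal maxima at two slices resolve to the lower index."""

        class _Stub:
            def __init__(self, probs):
                self.probs = probs

            def predict(self, flat):
                return np.stack([1 - self.probs, self.probs], axis=1)

        n = 20
        base = np.full(n, 0.1)
        tied = base.copy()
        tied[[11, 13]] = 0.9
        later = base.copy()
        later[15] = 0.9
        top = base.copy()
        top[18] = 0.9
        model = SliceDetectorModel(
            scorers={
                "key1": _Stub(tied),
                "key2": _Stub(later),
                "key3": _Stub(base.copy()),
                "key4": _Stub(top),
            },
            config=SliceDetectConfig(input_size=8),
        )
        stack = np.zeros((n, 8, 8), dtype=np.float32)
        ks = detect_key_slices(stack, model)
        assert ks.key1 == 11

    def test_missing_annotation_rejected(self, mini_subjects):
        broken = [mini_subjects[0], mini_subjects[1]]
        import copy

        nolabel = copy.copy(mini_subjects[2])
        nolabel.key_slices = None
        with pytest.raises(ValueError, match=nolabel.subject_id):
            train_slice_detector(broken + [nolabel] * 3, SliceDetectConfig(epochs=1))

    def test_training_determinism(self, mini_subjects):
        cfg = SliceDetectConfig(epochs=2, seed=9)
        a = train_slice_detector(mini_subjects, cfg)
        b = train_slice_detector(mini_subjects, cfg)
        assert a.report["folds"] == b.report["folds"]
        for name in KEY_NAMES:
            for wa, wb in zip(a.scorers[name].weights, b.scorers[name].weights):
                assert np.array_equal(wa, wb)

    def test_stack_shape_mismatch_reported(self, mini_bundle):
        bundle, _ = mini_bundle
        with pytest.raises(ValueError, match="input size"):
            score_slices(np.zeros((10, 16, 16), dtype=np.float32), bundle.detector)


# ---------------------------------------------------------------- measurement
class TestMeasurement:
    def test_fuse_adjacent_channels(self, untilted_phantom):
        _, volume, _ = untilted_phantom
        fused = fuse_adjacent(volume, 20)
        assert fused.channels.shape == (3, 224, 224)
        assert fused.mm_per_px == pytest.approx(0.45 * 512 / 224)

    def test_fuse_boundary_duplicates_edge_slice(self, untilted_phantom):
        _, volume, _ = untilted_phantom
        fused = fuse_adjacent(volume, 0)
        assert np.array_equal(fused.channels[0], fused.channels[1])

    def test_fuse_out_of_range_rejected(self, untilted_phantom):
        _, volume, _ = untilted_phantom
        with pytest.raises(IndexError):
            fuse_adjacent(volume, volume.n_slices)

    def test_fused_channels_are_consecutive_slices(self):
        stack = np.arange(5 * 2 * 2, dtype=np.float32).reshape(5, 2, 2)
        f = fused_channels(stack, 2)
        assert np.array_equal(f, stack[[1, 2, 3]])

    def test_oracle_is_identity_on_spec(self):
        spec = ph.sample_phantom_spec("severe", 17)
        m = oracle_measurements(spec)
        assert m.C == spec.third_ventricle_width_C
        assert m.HL == spec.sylvian_width_left_HL

    def test_prediction_contract(self, mini_subjects, mini_bundle):
        bundle, _ = mini_bundle
        s = mini_subjects[0]
        m, flags = predict_measurements(s, s.key_slices, bundle.measurement)
        values = m.as_array()
        assert values.shape == (9,)
        assert np.all(values > 0)

    def test_mm_outputs_scale_linearly_with_pixel_spacing(self, mini_bundle, untilted_phantom):
        bundle, _ = mini_bundle
        _, volume, annotation = untilted_phantom
        import dataclasses

        doubled = dataclasses.replace(volume, pixel_spacing=(0.9, 0.9))
        from ctatrophy.features import prepare_subject

        s1 = prepare_subject("a", volume, annotation, correct_tilt=False)
        s2 = prepare_subject("b", doubled, annotation, correct_tilt=False)
        m1, _ = predict_measurements(s1, annotation.key_slices, bundle.measurement)
        m2, _ = predict_measurements(s2, annotation.key_slices, bundle.measurement)
        assert np.allclose(m2.as_array(), 2.0 * m1.as_array(), rtol=1e-6)

    def test_non_positive_prediction_clamped_and_flagged(self, mini_subjects, mini_bundle):
        import copy

        bundle, _ = mini_bundle
        model = copy.deepcopy(bundle.measurement)
        net = model.heads["key3"]
        net.weights[-1][:] = 0.0
        net.biases[-1][:] = -1.0  # force negative widths
        s = mini_subjects[0]
        m, flags = predict_measurements(s, s.key_slices, model)
        assert m.HL == 0.5 and m.HR == 0.5
        assert set(flags) == {"HL", "HR"}

    def test_zero_epoch_training_flagged_as_degenerate(self, mini_subjects):
        model = train_measurement_model(mini_subjects, MeasureConfig(epochs=0))
        assert model.report["degenerate"] is True
        s = mini_subjects[0]
        a, _ = predict_measurements(s, s.key_slices, model)
        b, _ = predict_measurements(mini_subjects[1], mini_subjects[1].key_slices, model)
        # constant-bias predictor: same output for different subjects
        assert np.allclose(a.as_array(), b.as_array())

    def test_missing_annotations_rejected(self, mini_subjects):
        import copy

        bad = copy.copy(mini_subjects[0])
        bad.measurements = None
        with pytest.raises(ValueError, match=bad.subject_id):
            train_measurement_model([bad], MeasureConfig(epochs=1))

    def test_training_determinism(self, mini_subjects):
        cfg = MeasureConfig(epochs=3, seed=4)
        a = train_measurement_model(mini_subjects, cfg)
        b = train_measurement_model(mini_subjects, cfg)
        assert a.report["final_mse"] == b.report["final_mse"]


# --------------------------------------------------------------------- sulci
class TestSulci:
    @pytest.mark.parametrize(
        "widths,expected",
        [
            ([6.0, 6.5, 3.0], True),
            ([5.0, 5.0, 5.0], False),  # strict inequality at exactly 5 mm
            ([6.0, 4.0, 4.0], False),  # a single wide sulcus is not enough
            ([5.01, 5.01], True),
            ([4.0], False),
        ],
    )
    def test_rule_oracle(self, widths, expected):
        assert sulci_rule_oracle(widths) is expected

    def test_rule_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            sulci_rule_oracle([])
        with pytest.raises(ValueError):
            sulci_rule_oracle([3.0, -1.0])

    def test_result_threshold_convention(self):
        assert SulciResult(True, 0.73).enlarged
        assert SulciResult(True, 0.5).enlarged  # boundary inclusive
        with pytest.raises(ValueError):
            SulciResult(False, 0.73)

    def test_prediction_probability_in_range(self, mini_subjects, mini_bundle):
        bundle, _ = mini_bundle
        s = mini_subjects[3]
        res = predict_sulci(s, s.key_slices.key4, bundle.sulci)
        assert 0.0 <= res.probability <= 1.0
        assert res.enlarged == (res.probability >= 0.5)

    def test_invalid_slice_rejected(self, mini_subjects, mini_bundle):
        bundle, _ = mini_bundle
        with pytest.raises(IndexError):
            predict_sulci(mini_subjects[0], 99, bundle.sulci)

    def test_single_class_labels_rejected(self, mini_subjects):
        import copy

        allpos = []
        for s in mini_subjects[:6]:
            c = copy.copy(s)
            c.sulci_enlarged = True
            allpos.append(c)
        with pytest.raises(ValueError, match="single class"):
            train_sulci_classifier(allpos, SulciConfig(epochs=1))

    def test_training_determinism(self, mini_subjects):
        cfg = SulciConfig(epochs=2, seed=8)
        a = train_sulci_classifier(mini_subjects, cfg)
        b = train_sulci_classifier(mini_subjects, cfg)
        assert a.report["fold_accuracies"] == b.report["fold_accuracies"]


# ------------------------------------------------------------------ tiny nets
class TestMLP:
    def test_linear_head_fits_a_linear_map(self, rng):
        x = rng.normal(size=(200, 5)).astype(np.float32)
        w = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = x @ w
        net = MLP([5, 16, 1], task="linear", seed=0, l2=0.0)
        net.fit(x, y, epochs=300, batch_size=16, lr=0.01, optimizer="adam", standardize=False)
        pred = net.predict(x)[:, 0]
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_softmax_probabilities_normalized(self, rng):
        x = rng.normal(size=(50, 4)).astype(np.float32)
        y = (x[:, 0] > 0).astype(int)
        net = MLP([4, 8, 2], seed=1)
        net.fit(x, y, epochs=20, batch_size=8, lr=0.01)
        p = net.predict(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_serialization_roundtrip(self, rng):
        x = rng.normal(size=(30, 3)).astype(np.float32)
        y = (x[:, 0] > 0).astype(int)
        net = MLP([3, 4, 2], seed=2)
        net.fit(x, y, epochs=5, batch_size=8, lr=0.01)
        restored = MLP.from_arrays(net.to_arrays())
        assert np.array_equal(net.predict(x), restored.predict(x))
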