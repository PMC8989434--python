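"""Phantom generator: class-conditional sampling, rendering fidelity,
label-rule consistency and dataset reproducibility."""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pytest

from ctatrophy import phantom as ph


class TestSampling:
    def test_identical_class_seed_gives_identical_spec(self):
        a = ph.sample_phantom_spec("severe", 1)
        b = ph.sample_phantom_spec("severe", 1)
        assert a == b

    def test_unknown_class_rejected_with_allowed_labels(self):
        with pytest.raises(ValueError, match="no_atrophy"):
            ph.sample_phantom_spec("moderate", 0)

    def test_severe_has_at_least_two_wide_sulci(self):
        spec = ph.sample_phantom_spec("severe", 1)
        assert sum(w > 5.0 for w in spec.parietal_sulci_widths) >= 2

    def test_no_atrophy_has_no_wide_sulci(self):
        spec = ph.sample_phantom_spec("no_atrophy", 7)
        assert all(w <= 5.0 for w in spec.parietal_sulci_widths)

    def test_mild_fails_both_extreme_predicates(self):
        spec = ph.sample_phantom_spec("mild", 3)
        # not severe: cannot satisfy the enlarged-everywhere conjunction
        severe_pred = (
            sum(w > 5.0 for w in spec.parietal_sulci_widths) >= 2
            and spec.third_ventricle_width_C > 8.75
            and min(spec.sylvian_width_left_HL, spec.sylvian_width_right_HR) > 6.85
        )
        normal_pred = (
            spec.third_ventricle_width_C <= 6.25
            and max(spec.sylvian_width_left_HL, spec.sylvian_width_right_HR) <= 5.15
            and all(w <= 5.0 for w in spec.parietal_sulci_widths)
        )
        assert not severe_pred and not normal_pred

    @pytest.mark.parametrize("cls", ph.CLASSES)
    def test_label_rule_consistency(self, cls):
        """classify_spec applied to any sampled spec recovers its label."""
        for seed in range(40):
            spec = ph.sample_phantom_spec(cls, 5000 + seed)
            assert ph.classify_spec(spec) == cls
            spec.validate()

    def test_invariants_hold_on_samples(self):
        for seed in range(30):
            spec = ph.sample_phantom_spec(ph.CLASSES[seed % 3], seed)
            m = spec.measurements()
            assert m.F > m.E
            assert spec.choroid_plexus_distance_D > spec.intercaudate_distance_B
            assert abs(spec.head_tilt_deg) <= 10
            assert all(v > 0 for v in m.as_array())

    def test_class_conditional_third_ventricle_ordering(self):
        specs = ph.dataset_specs(50, 0)
        by_class = {c: [] for c in ph.CLASSES}
        for _, s in specs:
            by_class[s.atrophy_class].append(s.third_ventricle_width_C)
        assert np.mean(by_class["severe"]) > np.mean(by_class["mild"])
        assert np.mean(by_class["mild"]) > np.mean(by_class["no_atrophy"])


class TestRendering:
    def test_pixel_count_oracle_within_one_pixel(self, untilted_phantom):
        """Rendered widths along the measurement lines match the spec."""
        spec, volume, annotation = untilted_phantom
        measured = ph.pixel_count_measurements(volume, annotation)
        tol = volume.pixel_spacing[1] + 1e-9
        for name in ph.MeasurementSet.NAMES:
            assert abs(getattr(measured, name) - getattr(annotation.measurements, name)) <= tol

    def test_sulci_widths_render_within_one_pixel(self, untilted_phantom):
        spec, volume, annotation = untilted_phantom
        widths = ph.pixel_count_sulci_widths(volume, annotation)
        tol = volume.pixel_spacing[1] + 1e-9
        assert len(widths) == len(spec.parietal_sulci_widths)
        for got, want in zip(widths, sorted(spec.parietal_sulci_widths)):
            assert abs(got - want) <= tol

    def test_key4_is_third_slice_above_ventricle_top(self, untilted_phantom):
        _, _, annotation = untilted_phantom
        assert annotation.key_slices.key4 - annotation.top_ventricle_slice == 3

    def test_key_slice_ordering(self, untilted_phantom):
        _, volume, annotation = untilted_phantom
        annotation.key_slices.validate(volume.n_slices)

    def test_untilted_skull_mask_mirror_symmetric(self, untilted_phantom):
        _, volume, _ = untilted_phantom
        mid = volume.voxels[volume.n_slices // 2] >= 700
        flipped = mid[:, ::-1]
        # symmetric within one pixel: dilate by one column before comparing
        grown = mid | np.roll(mid, 1, axis=1) | np.roll(mid, -1, axis=1)
        assert np.all(flipped <= grown)

    def test_hu_ranges(self, untilted_phantom):
        _, volume, _ = untilted_phantom
        volume.validate()
        assert volume.voxels.max() >= 700.0  # skull present
        assert (volume.voxels >= 3071).mean() == 0

    def test_annotation_measurements_equal_spec(self, untilted_phantom):
        spec, _, annotation = untilted_phantom
        assert annotation.measurements == spec.measurements()

    def test_oversized_head_rejected(self):
        spec = ph.sample_phantom_spec("no_atrophy", 2)
        spec = dataclasses.replace(spec, extracranial_width_G=260.0, intracranial_width_F=240.0)
        with pytest.raises(ValueError, match="field of view"):
            ph.render_volume(spec)

    def test_render_deterministic(self):
        spec = ph.sample_phantom_spec("severe", 9)
        va, _ = ph.render_volume(spec)
        vb, _ = ph.render_volume(spec)
        assert np.array_equal(va.voxels, vb.voxels)


class TestDataset:
    def test_manifest_counts_and_determinism(self, tmp_path):
        m1 = ph.generate_dataset(2, 0, tmp_path / "a")
        assert len(m1) == 6
        assert (m1["atrophy_class"].value_counts() == 2).all()
        ph.generate_dataset(2, 0, tmp_path / "b")
        a = (tmp_path / "a" / "manifest.csv").read_text()
        b = (tmp_path / "b" / "manifest.csv").read_text()
        assert a.replace(str(tmp_path / "a"), "X") == b.replace(str(tmp_path / "b"), "X")
        for name in ("phantom_0000.json", "phantom_0003.json"):
            assert (tmp_path / "a" / name).read_text() == (tmp_path / "b" / name).read_text()

    def test_volume_roundtrip(self, tmp_path):
        sid, spec = ph.dataset_specs(1, 4)[0]
        volume, annotation = ph.render_volume(spec)
        ph.save_volume(volume, tmp_path / "v.nii.gz")
        loaded = ph.load_volume(tmp_path / "v.nii.gz")
        assert loaded.voxels.shape == volume.voxels.shape
        # NIfTI headers store zooms as float32
        assert loaded.pixel_spacing == pytest.approx(volume.pixel_spacing, rel=1e-6)
        assert loaded.slice_thickness == pytest.approx(volume.slice_thickness, rel=1e-6)
        # int16 storage: values preserved to rounding
        assert np.max(np.abs(loaded.voxels - volume.voxels)) <= 1.0

    def test_unwritable_directory_reported(self, tmp_path):
        target = tmp_path / "file"
        target.write_text("x")
        with pytest.raises(OSError, match=str(target)):
            ph.generate_dataset(1, 0, target)

    def test_n_per_class_validated(self, tmp_path):
        with pytest.raises(ValueError):
            ph.generate_dataset(0, 0, tmp_path)

    def test_annotation_json_roundtrip(self, tmp_path):
        ph.generate_dataset(1, 3, tmp_path)
        ann = ph.load_annotation(tmp_path / "phantom_0000.json")
        raw = json.loads(Path(tmp_path / "phantom_0000.json").read_text())
        assert ann.atrophy_class == raw["atrophy_class"]
        assert ann.key_slices.key4 == raw["key_slices"]["key4"]
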