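"""Loading, normalization, paired augmentation and leakage-free splits."""

import numpy as np
import pandas as pd
import pytest

from lispcn.cases import LongitudinalCase
from lispcn.dataio import (AUGMENT_OPS, AugmentStream, augment, load_cohort,
                           normalize, split_patients)
from lispcn.phantom import generate_cohort, write_cohort


def make_case(rng, size=8, patient="p0"):
    img = rng.uniform(-1, 1, (3, size, size)).astype(np.float32)
    img2 = rng.uniform(-1, 1, (3, size, size)).astype(np.float32)
    mask = (rng.random((size, size)) > 0.7).astype(np.uint8)
    return LongitudinalCase(patient, img, img2, mask, label=1)


class TestNormalize:
    def test_spans_unit_range(self, rng):
        out = normalize(rng.uniform(100, 900, (3, 32, 32)))
        assert out.min() == pytest.approx(-1, abs=1e-6)
        assert out.max() == pytest.approx(1, abs=1e-6)

    def test_constant_image_warns_all_minus_one(self):
        with pytest.warns(RuntimeWarning):
            out = normalize(np.full((3, 8, 8), 7.0))
        assert (out == -1).all()

    def test_scale_invariance(self, rng):
        raw = rng.uniform(0, 10, (3, 16, 16))
        np.testing.assert_allclose(normalize(raw), normalize(2 * raw),
                                   atol=1e-6)

    def test_monotone(self, rng):
        raw = rng.uniform(0, 1, (3, 16, 16))
        out = normalize(raw)
        flat_in, flat_out = raw.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-9).all()


class TestAugment:
    def test_rot90_four_times_is_identity(self, rng):
        case = make_case(rng)
        out = case
        for _ in range(4):
            out = augment(out, "rot90")
        np.testing.assert_array_equal(out.pre_image, case.pre_image)
        np.testing.assert_array_equal(out.lesion_mask, case.lesion_mask)

    def test_hflip_involution(self, rng):
        case = make_case(rng)
        out = augment(augment(case, "hflip"), "hflip")
        np.testing.assert_array_equal(out.early_image, case.early_image)

    def test_rot180_equals_hflip_then_vflip(self, rng):
        case = make_case(rng)
        a = augment(case, "rot180")
        b = augment(augment(case, "hflip"), "vflip")
        np.testing.assert_array_equal(a.pre_image, b.pre_image)
        np.testing.assert_array_equal(a.lesion_mask, b.lesion_mask)

    def test_same_transform_applied_to_all_planes(self, rng):
        case = make_case(rng)
        out = augment(case, "rot270")
        np.testing.assert_array_equal(
            out.pre_image, np.rot90(case.pre_image, 3, axes=(-2, -1)))
        np.testing.assert_array_equal(
            out.lesion_mask, np.rot90(case.lesion_mask, 3))
        assert out.label == case.label

    def test_op_set_closed_under_composition(self, rng):
        """The six ops land inside the dihedral-4 subgroup they span."""
        case = make_case(rng)
        reachable = []
        import itertools
        for op in AUGMENT_OPS:
            reachable.append(augment(case, op).pre_image)
        for op1, op2 in itertools.product(AUGMENT_OPS, repeat=2):
            composed = augment(augment(case, op1), op2).pre_image
            dihedral8 = reachable + [
                np.flip(r, axis=-1) for r in reachable]
            assert any(np.array_equal(composed, r) for r in dihedral8)

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment(make_case(rng), "rot45")

    def test_stream_is_seeded(self, rng):
        case = make_case(rng)
        a = AugmentStream(5)
        b = AugmentStream(5)
        for _ in range(10):
            np.testing.assert_array_equal(a(case).pre_image,
                                          b(case).pre_image)


class TestSplits:
    def frame(self, n_pat, slices=1, seed=0):
        r = np.random.default_rng(seed)
        rows = []
        for i in range(n_pat):
            label = int(r.random() < 0.3)
            for _ in range(slices):
                rows.append({"patient_id": f"p{i:03d}", "label": label})
        return pd.DataFrame(rows)

    def test_basic_disjoint_split(self):
        plan = split_patients(self.frame(10), (0.8, 0.2), seed=1,
                              split_names=("train", "test"))
        assert len(plan.patients("train")) == 8
        assert len(plan.patients("test")) == 2
        assert not set(plan.patients("train")) & set(plan.patients("test"))

    def test_multislice_patients_never_straddle_splits(self):
        frame = self.frame(20, slices=3)
        plan = split_patients(frame, (0.6, 0.2, 0.2), seed=3)
        for pid, grp in frame.groupby("patient_id"):
            assert len({plan.assignment[pid]}) == 1

    def test_zero_leakage_over_many_seeds(self):
        frame = self.frame(50, slices=3)
        for seed in range(20):
            plan = split_patients(frame, (0.7, 0.3), seed=seed,
                                  split_names=("train", "test"))
            tr = set(plan.patients("train"))
            te = set(plan.patients("test"))
            assert len(tr & te) == 0
            assert tr | te == set(frame.patient_id)

    def test_deterministic_given_seed(self):
        frame = self.frame(15)
        a = split_patients(frame, (0.5, 0.5), seed=9)
        b = split_patients(frame, (0.5, 0.5), seed=9)
        assert a.assignment == b.assignment

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_patients(self.frame(10), (0.5, 0.4), seed=0)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            split_patients(self.frame(2), (0.4, 0.3, 0.3), seed=0)

    def test_stratification_keeps_both_classes_in_test(self):
        frame = self.frame(40, seed=4)
        plan = split_patients(frame, (0.8, 0.2), seed=0,
                              split_names=("train", "test"))
        labels = frame.groupby("patient_id").label.first()
        test_labels = labels[plan.patients("test")]
        assert test_labels.nunique() == 2


class TestLoadCohort:
    def test_label_validation(self, tmp_path):
        cases = generate_cohort(2, 0.3, 32, seed=0, slices_per_patient=1)
        manifest = write_cohort(cases, str(tmp_path))
        frame = pd.read_csv(manifest)
        frame.loc[0, "label"] = 2
        bad = tmp_path / "bad.csv"
        frame.to_csv(bad, index=False)
        with pytest.raises(ValueError, match="non-binary label"):
            load_cohort(str(bad))

    def test_missing_file_reported(self, tmp_path):
        cases = generate_cohort(2, 0.3, 32, seed=0, slices_per_patient=1)
        manifest = write_cohort(cases, str(tmp_path))
        frame = pd.read_csv(manifest)
        frame.loc[0, "pre_path"] = str(tmp_path / "nope.nii.gz")
        bad = tmp_path / "bad.csv"
        frame.to_csv(bad, index=False)
        with pytest.raises(FileNotFoundError, match=frame.loc[0, "patient_id"]):
            load_cohort(str(bad))

    def test_shape_mismatch_names_patient(self, tmp_path):
        import imageio.v3 as iio
        cases = generate_cohort(2, 0.3, 32, seed=0, slices_per_patient=1)
        manifest = write_cohort(cases, str(tmp_path))
        frame = pd.read_csv(manifest)
        iio.imwrite(frame.loc[0, "mask_path"],
                    np.zeros((16, 16), dtype=np.uint8))
        with pytest.raises(ValueError, match=frame.loc[0, "patient_id"]):
            load_cohort(manifest)
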