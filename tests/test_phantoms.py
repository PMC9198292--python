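"""Synthetic multimodal phantom generator: determinism, ground-truth bookkeeping."""

import numpy as np
import pytest

from npvreg import (
    AffineTransform,
    make_registration_case,
    make_shape_phantom,
    nmi,
    new_histogram,
    npv_accumulate,
    random_class_remap,
    sample_grid,
    simulate_modality,
)
from npvreg.errors import MappingError, OutOfFrameError, SizeError
from npvreg.phantoms import load_case, save_case
from npvreg.similarity import marginal_entropies
from npvreg.transforms import ffd_displacement, warp_image


class TestShapePhantom:
    def test_class_count(self):
        img = make_shape_phantom((64, 64), 3, seed=1)
        assert len(np.unique(img.data)) == 4  # 3 classes + background

    def test_determinism(self):
        a = make_shape_phantom((64, 64), 4, seed=7)
        b = make_shape_phantom((64, 64), 4, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_seed_changes_image(self):
        a = make_shape_phantom((64, 64), 4, seed=7)
        b = make_shape_phantom((64, 64), 4, seed=8)
        assert not np.array_equal(a.data, b.data)

    def test_too_small_rejected(self):
        with pytest.raises(SizeError):
            make_shape_phantom((8, 8), 2, seed=0)

    def test_3d_supported(self):
        img = make_shape_phantom((24, 24, 24), 2, seed=3)
        assert img.ndim == 3
        assert len(np.unique(img.data)) == 3

    def test_background_zero_and_range(self):
        img = make_shape_phantom((64, 64), 5, seed=2)
        assert img.data[0, 0] == 0.0
        assert img.data.max() <= 255
        assert img.data.min() == 0.0


class TestSimulateModality:
    def test_identity_remap_no_noise(self):
        img = make_shape_phantom((64, 64), 3, seed=1)
        remap = {float(v): float(v) for v in np.unique(img.data)}
        out = simulate_modality(img, remap, 0.0)
        assert np.array_equal(out.data, img.data)

    def test_missing_class_rejected(self):
        img = make_shape_phantom((64, 64), 3, seed=1)
        with pytest.raises(MappingError):
            simulate_modality(img, {0.0: 0.0}, 0.0)

    def test_noise_reproducible(self):
        img = make_shape_phantom((64, 64), 3, seed=1)
        remap = random_class_remap(img, seed=2)
        a = simulate_modality(img, remap, 5.0, seed=9)
        b = simulate_modality(img, remap, 5.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_permuted_remap_is_functional(self):
        """Non-monotone remap, sigma=0: one nonzero column per occupied row."""
        img = make_shape_phantom((64, 64), 4, seed=5)
        remap = random_class_remap(img, seed=6)
        out = simulate_modality(img, remap, 0.0)
        samples = sample_grid(img, 1)
        hist = npv_accumulate(
            new_histogram(64), img, out, AffineTransform.identity(2), samples
        )
        for row in hist.counts:
            assert np.count_nonzero(row) <= 1

    def test_functional_dependence_gives_mi_of_marginal(self):
        """With a class permutation and no noise, MI = H(reference marginal)."""
        img = make_shape_phantom((64, 64), 4, seed=5)
        remap = random_class_remap(img, seed=6)
        out = simulate_modality(img, remap, 0.0)
        samples = sample_grid(img, 1)
        hist = npv_accumulate(
            new_histogram(64), img, out, AffineTransform.identity(2), samples
        )
        h_r, h_f = marginal_entropies(hist)
        assert h_f == pytest.approx(h_r, abs=1e-9)
        assert nmi(hist) == pytest.approx(2.0, abs=1e-9)


class TestRegistrationCase:
    def test_zero_translation_records_zero(self):
        case = make_registration_case((64, 64), "translation", 0.0, 2.0, seed=1)
        assert np.allclose(case.true_transform.translation, 0.0)
        assert case.reference.shape == case.floating.shape

    def test_translation_bookkeeping(self):
        case = make_registration_case(
            (64, 64), "translation", (3.5, -2.25), 0.0, seed=1
        )
        assert np.array_equal(case.true_transform.translation, [3.5, -2.25])

    def test_ffd_displacement_bounded_by_magnitude(self):
        case = make_registration_case((64, 64), "ffd", 4.0, 0.0, seed=2)
        coords = np.indices((64, 64)).reshape(2, -1).T.astype(float)
        disp = case.true_transform(coords) - coords
        assert np.max(np.abs(disp)) <= 4.0 + 1e-9

    def test_determinism(self):
        a = make_registration_case((64, 64), "rigid", 8.0, 2.0, seed=4)
        b = make_registration_case((64, 64), "rigid", 8.0, 2.0, seed=4)
        assert np.array_equal(a.floating.data, b.floating.data)
        assert np.array_equal(a.reference.data, b.reference.data)

    def test_out_of_frame_rejected(self):
        with pytest.raises(OutOfFrameError):
            make_registration_case((64, 64), "translation", (30.0, 0.0), 0.0, seed=1)

    def test_inverse_warp_and_remap_recover_reference(self):
        """Integer translation, exact inverse: MAE over interior <= 3 sigma."""
        sigma = 2.0
        case = make_registration_case(
            (64, 64), "translation", (3.0, -2.0), sigma, seed=6
        )
        back = warp_image(case.floating, case.true_transform.inverse(), "nearest")
        inverse_remap = {v: k for k, v in case.modality_remap.items()}
        undone = np.zeros_like(back.data)
        class_values = np.array(sorted(inverse_remap))
        nearest = class_values[
            np.argmin(np.abs(back.data[..., None] - class_values), axis=-1)
        ]
        for v in class_values:
            undone[nearest == v] = inverse_remap[float(v)]
        interior = np.s_[6:-6, 6:-6]
        mae = np.abs(undone[interior] - case.reference.data[interior]).mean()
        assert mae <= 3 * sigma

    def test_round_trip_serialization(self, tmp_path):
        case = make_registration_case((64, 64), "rigid", 7.0, 2.0, seed=3)
        save_case(case, tmp_path / "case", fmt="nii.gz")
        back = load_case(tmp_path / "case")
        assert np.array_equal(back.reference.data, case.reference.data)
        assert np.array_equal(back.floating.data, case.floating.data)
        assert np.allclose(back.true_transform.matrix, case.true_transform.matrix)
        assert back.modality_remap == case.modality_remap

    def test_composed_case_ground_truth_shape(self):
        case = make_registration_case(
            (64, 64), "rigid+ffd", (5.0, 2.0), 2.0, seed=8
        )
        coords = np.indices((64, 64)).reshape(2, -1).T.astype(float)
        disp = case.true_transform(coords) - coords
        assert np.isfinite(disp).all()
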