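import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermotrack import (
    FeatureVector,
    blob_features,
    dct_parameterize,
    detect,
    energy_fraction,
    extract_signature,
    normalize_signature,
    outer_contour,
    perimeter_contour,
    reconstruct_signature,
)
from thermotrack.detection import Blob, DetectionParams

from conftest import make_frame, random_blob_mask


def mask_blob(mask, frame_index=0):
    rows, cols = np.nonzero(mask)
    return Blob(rows=rows, cols=cols, frame_index=frame_index)


def dct_double_sum(x):
    """Direct O(N^2) orthonormal type-II DCT oracle, scaled by 1/sqrt(N)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.zeros(n)
    for k in range(n):
        a = math.sqrt(1.0 / n) if k == 0 else math.sqrt(2.0 / n)
        out[k] = a * sum(
            x[i] * math.cos(math.pi * k * (2 * i + 1) / (2 * n)) for i in range(n)
        )
    return out / math.sqrt(n)


class TestContours:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert set(zip(*np.nonzero(outer_contour(mask)))) == {
            (1, 2), (3, 2), (2, 1), (2, 3)
        }
        assert np.array_equal(perimeter_contour(mask), mask)

    def test_three_by_three_square(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[2:5, 2:5] = True
        ring = outer_contour(mask)
        expected = {(1, c) for c in (2, 3, 4)} | {(5, c) for c in (2, 3, 4)}
        expected |= {(r, 1) for r in (2, 3, 4)} | {(r, 5) for r in (2, 3, 4)}
        assert set(zip(*np.nonzero(ring))) == expected
        perim = perimeter_contour(mask)
        assert perim.sum() == 8 and not perim[3, 3]

    def test_line_is_all_perimeter(self):
        mask = np.zeros((3, 7), dtype=bool)
        mask[1, 1:6] = True
        assert np.array_equal(perimeter_contour(mask), mask)

    def test_full_frame_mask_has_empty_ring(self):
        mask = np.ones((4, 4), dtype=bool)
        assert not outer_contour(mask).any()


class TestExtractSignature:
    def test_square_oracle(self, square_frame):
        sig = extract_signature(square_frame, detect(square_frame)[0])
        assert np.allclose(sig.samples, [20.0, 30.0, 30.0])
        assert sig.contour_sizes.tolist() == [12, 8, 1]
        assert sig.M == 1
        assert not sig.border_clipped

    def test_uniform_blob_has_flat_interior(self, rng):
        mask = random_blob_mask(rng)
        vals = np.full(mask.shape, 18.0)
        vals[mask] = 31.0
        sig = extract_signature(make_frame(vals), mask_blob(mask))
        assert np.allclose(sig.samples[1:], 31.0)

    def test_radial_gradient_gives_increasing_signature(self):
        h = w = 21
        rr, cc = np.mgrid[0:h, 0:w]
        r = np.hypot(rr - 10, cc - 10)
        vals = 20.0 + np.where(r <= 8, 10.0 * (1 - r / 9.0), 0.0)
        frame = make_frame(vals)
        blob = detect(frame, DetectionParams(c=1.0))[0]
        sig = extract_signature(frame, blob)
        interior = sig.samples[1:]
        assert np.all(np.diff(interior) > 0)

    def test_contour_partition_and_termination(self, rng):
        """Peeled contours are disjoint and exactly tile the blob."""
        for _ in range(10):
            mask = random_blob_mask(rng)
            vals = rng.uniform(15, 35, size=mask.shape)
            sig = extract_signature(make_frame(vals), mask_blob(mask))
            assert sig.contour_sizes[1:].sum() == mask.sum()
            assert len(sig.samples) - 1 <= mask.sum() + 1  # terminates
            assert sig.M + 2 == len(sig.samples)

    def test_translation_invariance(self, rng):
        mask = random_blob_mask(rng, shape=(16, 16))
        vals = rng.uniform(15, 35, size=(16, 16))
        big_vals = np.full((30, 30), 10.0)
        big_mask = np.zeros((30, 30), dtype=bool)
        sigs = []
        for dr, dc in ((2, 2), (9, 11)):
            v = big_vals.copy()
            m = big_mask.copy()
            v[dr:dr + 16, dc:dc + 16] = vals
            m[dr:dr + 16, dc:dc + 16] = mask
            sigs.append(extract_signature(make_frame(v), mask_blob(m)))
        assert np.array_equal(sigs[0].samples, sigs[1].samples)
        assert np.array_equal(sigs[0].contour_sizes, sigs[1].contour_sizes)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_right_angle_rotation_invariance(self, rng, k):
        mask = random_blob_mask(rng)
        vals = rng.uniform(15, 35, size=mask.shape)
        vals[~mask] = 12.0
        base = extract_signature(make_frame(vals), mask_blob(mask))
        rot = extract_signature(
            make_frame(np.rot90(vals, k)), mask_blob(np.rot90(mask, k))
        )
        # identical pixel multisets; means differ only by summation order
        assert np.allclose(base.samples, rot.samples, atol=1e-12)
        assert np.array_equal(base.contour_sizes, rot.contour_sizes)

    def test_border_blob_flagged(self):
        vals = np.full((5, 5), 20.0)
        vals[0:2, 0:2] = 30.0
        frame = make_frame(vals)
        blob = detect(frame)[0]
        sig = extract_signature(frame, blob)
        assert sig.border_clipped
        assert sig.samples[0] == pytest.approx(20.0)  # ring mean, clipped

    def test_frame_filling_blob_falls_back_to_interior(self):
        vals = np.full((3, 3), 30.0)
        frame = make_frame(vals)
        blob = mask_blob(np.ones((3, 3), dtype=bool))
        sig = extract_signature(frame, blob)
        assert sig.border_clipped
        assert sig.samples[0] == sig.samples[1]


class TestNormalize:
    def test_subtracts_outer_ring_mean(self, square_frame):
        sig = extract_signature(square_frame, detect(square_frame)[0])
        assert np.allclose(normalize_signature(sig), [0.0, 10.0, 10.0])
        assert normalize_signature(sig)[0] == 0.0

    def test_interior_baseline_switch(self, square_frame):
        sig = extract_signature(square_frame, detect(square_frame)[0])
        assert np.allclose(normalize_signature(sig, baseline="interior"),
                           [-10.0, 0.0, 0.0])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12),
           st.floats(-20, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additive_shift_invariance(self, samples, shift):
        from thermotrack.signatures import ThermalSignature

        sig = ThermalSignature(samples=np.array(samples),
                               contour_sizes=np.ones(len(samples), dtype=int))
        shifted = ThermalSignature(samples=np.array(samples) + shift,
                                   contour_sizes=np.ones(len(samples), dtype=int))
        assert np.allclose(normalize_signature(sig),
                           normalize_signature(shifted), atol=1e-9)


class TestDCT:
    @pytest.mark.parametrize("n", [1, 3, 7, 12])
    def test_matches_double_sum_oracle(self, rng, n):
        x = rng.normal(size=n)
        fv = dct_parameterize(x, n_coeff=n)
        assert np.allclose(fv.coefficients, dct_double_sum(x)[:n], atol=1e-10)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_constant_input_is_length_invariant(self, n):
        fv = dct_parameterize(np.full(n, 4.5), n_coeff=7)
        assert fv.coefficients[0] == pytest.approx(4.5)
        assert np.allclose(fv.coefficients[1:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_cosine_basis_vector_hits_single_coefficient(self, k):
        n = 16
        i = np.arange(n)
        basis = np.cos(np.pi * k * (2 * i + 1) / (2 * n))
        fv = dct_parameterize(basis, n_coeff=7)
        nonzero = np.nonzero(np.abs(fv.coefficients) > 1e-9)[0]
        assert nonzero.tolist() == [k]

    def test_short_signature_zero_padded(self):
        fv = dct_parameterize(np.array([1.0, 2.0, 3.0]), n_coeff=7)
        assert fv.n_coeff == 7
        assert np.allclose(fv.coefficients[3:], 0.0)

    def test_round_trip_without_truncation(self, rng):
        x = rng.normal(size=7)
        fv = dct_parameterize(x, n_coeff=7)
        assert np.allclose(reconstruct_signature(fv, 7), x, atol=1e-10)
        const = dct_parameterize(np.full(5, 2.0), n_coeff=7)
        assert np.allclose(reconstruct_signature(const, 5), 2.0)

    def test_truncation_residual_obeys_parseval(self, rng):
        from scipy import fft

        x = rng.normal(size=20)
        coeffs = fft.dct(x, norm="ortho")
        fv = dct_parameterize(x, n_coeff=7)
        recon = reconstruct_signature(fv, 20)
        residual = np.sum((x - recon) ** 2)
        assert residual == pytest.approx(np.sum(coeffs[7:] ** 2), abs=1e-9)


class TestEnergyFraction:
    def test_total_retention_cases(self):
        assert energy_fraction(np.array([1.0, -2.0, 3.0]), 7) == 1.0
        n = 16
        i = np.arange(n)
        basis3 = np.cos(np.pi * 3 * (2 * i + 1) / (2 * n))
        assert energy_fraction(basis3, 7) == pytest.approx(1.0)
        assert energy_fraction(np.zeros(5), 3) == 1.0

    def test_equal_mixture_splits_energy(self):
        n = 16
        i = np.arange(n)
        b1 = np.cos(np.pi * 1 * (2 * i + 1) / (2 * n))
        b10 = np.cos(np.pi * 10 * (2 * i + 1) / (2 * n))
        assert energy_fraction(b1 + b10, 7) == pytest.approx(0.5)


def test_feature_pipeline_invariant_to_absolute_temperature(rng):
    """Adding a constant to every pixel changes no DCT coefficient."""
    mask = random_blob_mask(rng)
    vals = rng.uniform(15, 35, size=mask.shape)
    frame1 = make_frame(vals)
    frame2 = make_frame(vals + 6.7)
    blob = mask_blob(mask)
    fv1 = blob_features(frame1, blob)
    fv2 = blob_features(frame2, blob)
    assert np.allclose(fv1.coefficients, fv2.coefficients, atol=1e-9)


def test_signature_dct_transformer(rng, square_frame):
    from sklearn.pipeline import make_pipeline
    from thermotrack import SignatureDCT

    sig = extract_signature(square_frame, detect(square_frame)[0])
    t = SignatureDCT(n_coeff=7)
    X = t.fit_transform([sig, normalize_signature(sig)])
    assert X.shape == (2, 7)
    assert np.allclose(X[0], X[1])  # signature route normalizes internally
    assert t.get_params() == {"n_coeff": 7, "baseline": "outer"}
    pipe = make_pipeline(SignatureDCT(n_coeff=5))
    assert pipe.fit_transform([sig]).shape == (1, 5)
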