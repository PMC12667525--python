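"""Feature extraction, matrix assembly, scaling and selection."""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from fibroscreen.features import (
    FEATURE_NAMES,
    FeatureMatrix,
    OrganoidFeatures,
    build_matrix,
    extract_features,
    select_features,
    zscore,
)
from fibroscreen.imaging import (
    ProjectedImage,
    StackMetadata,
    count_nuclei,
    max_intensity_projection,
    segment_stack,
)
from fibroscreen.synthetic import simulate_organoid

from .conftest import feature_matrix_from_arrays, full_feature_row, small_spec

META = StackMetadata("o1", "NC", 21, "B1")


def projected(fib: np.ndarray, nuc: np.ndarray) -> ProjectedImage:
    return ProjectedImage(fibrosis=fib, nuclei=nuc, metadata=META)


def quantify(projection: ProjectedImage) -> OrganoidFeatures:
    masks = segment_stack(projection)
    n = count_nuclei(projection.nuclei, mask=masks.nuclei.mask)
    return extract_features(projection, masks, n)


class TestExtractFeatures:
    def test_exactly_18_named_features(self):
        assert len(FEATURE_NAMES) == 18
        stack, _ = simulate_organoid(small_spec(seed=2))
        feats = quantify(max_intensity_projection(stack))
        assert tuple(feats.values) == FEATURE_NAMES

    def test_blank_image_gives_degenerate_zeros(self):
        blank = np.zeros((64, 64))
        feats = quantify(projected(blank, blank))
        assert feats.empty_roi
        assert feats.values["fibrosis_intden"] == 0.0
        assert feats.values["nuclei_count"] == 0.0
        assert feats.values["fibrosis_area_fraction"] == 0.0
        assert feats.values["organoid_area_px"] == 0.0

    def test_uniform_disk_intden_closed_form(self):
        # disk of area A at intensity I on zero background: IntDen = A * I
        img = np.zeros((128, 128))
        rr, cc = draw_disk((64, 64), 20, shape=img.shape)
        img[rr, cc] = 500.0
        feats = quantify(projected(img, np.zeros_like(img)))
        assert feats.values["fibrosis_intden"] == pytest.approx(
            len(rr) * 500.0, rel=0.05
        )

    def test_simulated_intden_within_10pct_of_truth(self):
        for seed in (501, 502, 503, 504):
            stack, truth = simulate_organoid(small_spec(seed=seed))
            feats = quantify(max_intensity_projection(stack))
            assert feats.values["fibrosis_intden"] == pytest.approx(
                truth.true_fibrosis_integrated_intensity, rel=0.10
            )

    def test_area_fraction_bounded_and_masks_checked(self):
        stack, _ = simulate_organoid(small_spec(seed=6))
        proj = max_intensity_projection(stack)
        feats = quantify(proj)
        assert 0.0 <= feats.values["fibrosis_area_fraction"] <= 1.0
        assert 0.0 <= feats.values["organoid_solidity"] <= 1.0
        masks = segment_stack(proj)
        bad = ProjectedImage(
            fibrosis=proj.fibrosis[:-1, :-1], nuclei=proj.nuclei[:-1, :-1],
            metadata=proj.metadata,
        )
        with pytest.raises(ValueError, match="shape"):
            extract_features(bad, masks, 0)

    def test_feature_vector_validates_names_and_finiteness(self):
        good = full_feature_row(np.random.default_rng(0))
        incomplete = dict(good)
        incomplete.pop("nuclei_count")
        with pytest.raises(ValueError, match="mismatch"):
            OrganoidFeatures(metadata=META, values=incomplete)
        with_nan = dict(good, fibrosis_intden=float("nan"))
        with pytest.raises(ValueError, match="finite"):
            OrganoidFeatures(metadata=META, values=with_nan)


class TestBuildMatrix:
    def _features(self, n, rng):
        return [
            OrganoidFeatures(
                metadata=StackMetadata(f"org{i}", "NC", 21, "B1"),
                values=full_feature_row(rng),
            )
            for i in range(n)
        ]

    def test_three_organoids_give_3x18(self):
        m = build_matrix(self._features(3, np.random.default_rng(1)))
        assert m.values.shape == (3, 18)
        assert not m.scaled
        assert list(m.values.columns) == list(FEATURE_NAMES)

    def test_duplicate_organoid_id_rejected(self):
        rng = np.random.default_rng(2)
        feats = self._features(2, rng)
        feats.append(
            OrganoidFeatures(
                metadata=StackMetadata("org0", "NC", 21, "B1"),
                values=full_feature_row(rng),
            )
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(feats)

    def test_empty_roi_organoids_dropped(self):
        rng = np.random.default_rng(3)
        feats = self._features(3, rng)
        feats.append(
            OrganoidFeatures(
                metadata=StackMetadata("orgX", "NC", 21, "B1"),
                values=full_feature_row(rng),
                empty_roi=True,
            )
        )
        m = build_matrix(feats)
        assert m.n_organoids == 3
        assert "orgX" not in m.values.index

    def test_screen_scale_matrix_builds_quickly(self):
        # the reference screen scale is ~16k organoids; assembly must not
        # be the bottleneck
        rng = np.random.default_rng(4)
        feats = [
            OrganoidFeatures(
                metadata=StackMetadata(f"org{i}", f"T{i % 28}", 21, f"B{i % 4}"),
                values=full_feature_row(rng),
            )
            for i in range(16_333)
        ]
        t0 = time.perf_counter()
        m = build_matrix(feats)
        assert time.perf_counter() - t0 < 5.0
        assert m.values.shape == (16_333, 18)


class TestZScore:
    def test_hand_computed_column(self):
        m = feature_matrix_from_arrays(
            np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]), ["A", "A", "B"]
        )
        z = zscore(m)
        np.testing.assert_allclose(z.values["f0"], [-1.0, 0.0, 1.0])
        assert z.scaled
        # constant column flagged and zeroed
        assert z.constant_features == ["f1"]
        assert (z.values["f1"] == 0.0).all()

    def test_columns_standardized_within_1e9(self):
        rng = np.random.default_rng(5)
        m = feature_matrix_from_arrays(
            rng.normal(3.0, 2.0, size=(40, 6)), ["A"] * 20 + ["B"] * 20
        )
        z = zscore(m)
        assert np.abs(z.values.mean(axis=0)).max() < 1e-9
        assert np.abs(z.values.std(axis=0, ddof=1) - 1.0).max() < 1e-9

    def test_zscoring_twice_equals_once(self):
        rng = np.random.default_rng(6)
        m = feature_matrix_from_arrays(
            rng.normal(size=(25, 4)), ["A"] * 12 + ["B"] * 13
        )
        once = zscore(m)
        twice = zscore(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_single_organoid_rejected(self):
        m = feature_matrix_from_arrays(np.array([[1.0, 2.0]]), ["A"])
        with pytest.raises(ValueError, match="2 organoids"):
            zscore(m)

    def test_global_gain_leaves_zscores_unchanged(self):
        # multiplying every raw intensity by a constant gain is absorbed by
        # standardization
        rng = np.random.default_rng(7)
        raw = rng.uniform(1.0, 10.0, size=(30, 5))
        t = ["A"] * 15 + ["B"] * 15
        z1 = zscore(feature_matrix_from_arrays(raw, t))
        z2 = zscore(feature_matrix_from_arrays(raw * 3.7, t))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)


class TestSelectFeatures:
    def _matrix(self, rng):
        # two features separate treatments strongly, two are pure noise,
        # one is constant
        n = 60
        treatments = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        values = np.column_stack(
            [
                np.repeat([0.0, 5.0, 10.0], 20) + rng.normal(0, 0.5, n),
                np.repeat([0.0, 3.0, 6.0], 20) + rng.normal(0, 0.5, n),
                rng.normal(0, 1.0, n),
                rng.normal(2.0, 1.0, n),
                np.full(n, 4.2),
            ]
        )
        return feature_matrix_from_arrays(
            values, treatments,
            feature_names=["f_sig1", "f_sig2", "f_noise1", "f_noise2", "f_const"],
        )

    def test_between_treatment_signal_retained_noise_dropped(self):
        m = self._matrix(np.random.default_rng(8))
        sel = select_features(m, variance_quantile=0.5)
        assert {"f_sig1", "f_sig2"} <= set(sel.selected_features)
        assert "f_noise1" not in sel.selected_features
        assert "f_noise2" not in sel.selected_features

    def test_constant_feature_always_dropped(self):
        m = self._matrix(np.random.default_rng(9))
        for q in (0.0, 0.25, 0.5):
            sel = select_features(m, variance_quantile=q)
            assert "f_const" not in sel.selected_features

    def test_quantile_zero_keeps_all_nonconstant(self):
        m = self._matrix(np.random.default_rng(10))
        sel = select_features(m, variance_quantile=0.0)
        assert sorted(sel.selected_features) == [
            "f_noise1", "f_noise2", "f_sig1", "f_sig2"
        ]

    def test_at_least_two_features_survive(self):
        m = self._matrix(np.random.default_rng(11))
        sel = select_features(m, variance_quantile=0.9)
        assert len(sel.selected_features) >= 2

    def test_single_treatment_rejected(self):
        m = feature_matrix_from_arrays(
            np.random.default_rng(12).normal(size=(10, 3)), ["A"] * 10
        )
        with pytest.raises(ValueError, match="treatments"):
            select_features(m)


class TestMonotoneResponse:
    def test_mean_fibrosis_features_increase_with_effect(self):
        # construction: expected fibrotic intensity and area rise linearly
        # with the effect, so treatment means must be strictly ordered
        from fibroscreen.pipeline import quantify_stack
        from fibroscreen.imaging import SegmentationParams

        params = SegmentationParams()
        intden_means, area_frac_means = [], []
        for eff in (0.4, 0.8, 1.2, 1.6, 2.0):
            intdens, fracs = [], []
            for rep in range(10):
                stack, _ = simulate_organoid(
                    small_spec(fibrosis_effect=eff, seed=50_000 + rep)
                )
                f = quantify_stack(stack, params)
                intdens.append(f.values["fibrosis_intden"])
                fracs.append(f.values["fibrosis_area_fraction"])
            intden_means.append(np.mean(intdens))
            area_frac_means.append(np.mean(fracs))
        assert np.all(np.diff(intden_means) > 0)
        assert np.all(np.diff(area_frac_means) > 0)


class TestRoundTrip:
    def test_tsv_round_trip_preserves_matrix(self, tmp_path):
        rng = np.random.default_rng(13)
        m = feature_matrix_from_arrays(
            rng.normal(size=(8, 4)), ["A"] * 4 + ["B"] * 4,
            days=[17] * 4 + [21] * 4, batches=["B1", "B2"] * 4,
        )
        path = tmp_path / "features.tsv"
        m.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        np.testing.assert_allclose(back.values, m.values, rtol=1e-9)
        pd.testing.assert_frame_equal(back.labels, m.labels)
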