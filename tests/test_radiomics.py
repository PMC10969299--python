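"""Radiomic preprocessing, the 107-feature contract, and concatenation."""

import numpy as np
import pytest

from physiomap.radiomics import (CATEGORY_MAPS, DiscretizationPolicy, FEATURE_NAMES,
                                 FEATURE_CLASS_COUNTS, assemble_vector,
                                 default_biomarker_policies, extract_features,
                                 preprocess_map)


@pytest.fixture(scope="module")
def ellipsoid_mask():
    x, y, z = np.ogrid[:20, :20, :20]
    return ((x - 10) / 5.0) ** 2 + ((y - 10) / 6.0) ** 2 + ((z - 10) / 4.0) ** 2 <= 1


class TestPolicy:
    def test_manifest_counts(self):
        assert len(FEATURE_NAMES) == 107
        assert FEATURE_CLASS_COUNTS == {"shape": 14, "firstorder": 18, "glcm": 24,
                                        "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_unit_range_with_64_bins_inside_target_window(self):
        pol = DiscretizationPolicy.for_range(0.0, 1.0, 64)
        assert pol.bin_width == pytest.approx(1 / 64)
        n_bins = int(np.ceil(1.0 / pol.bin_width))
        assert 60 <= n_bins <= 67

    def test_out_of_window_bin_width_rejected(self):
        with pytest.raises(ValueError, match="outside the target"):
            DiscretizationPolicy(mode="range_binwidth", bin_width=0.5, value_range=(0, 1))

    def test_default_policies_cover_all_category_maps(self):
        pols = default_biomarker_policies()
        for cat, maps in CATEGORY_MAPS.items():
            for m in maps:
                assert m in pols


class TestPreprocess:
    def test_constant_image_occupies_single_bin(self, ellipsoid_mask):
        disc, rmask, _ = preprocess_map(np.full((20, 20, 20), 0.4), ellipsoid_mask,
                                        DiscretizationPolicy.for_range(0, 1))
        assert np.unique(disc[rmask]).size == 1

    def test_zscore_normalisation_over_mask(self, ellipsoid_mask, rng):
        vol = rng.normal(120.0, 30.0, (20, 20, 20))
        _, _, vals = preprocess_map(vol, ellipsoid_mask, DiscretizationPolicy(),
                                    norm_mask=np.ones((20, 20, 20), bool))
        assert vals.mean() == pytest.approx(0.0, abs=1e-9)
        assert vals.std() == pytest.approx(1.0, rel=1e-9)

    def test_resampling_to_isotropic_grid(self, ellipsoid_mask, rng):
        vol = rng.random((20, 20, 20))
        disc, rmask, _ = preprocess_map(vol, ellipsoid_mask,
                                        DiscretizationPolicy.for_range(0, 1),
                                        spacing=(2.0, 2.0, 2.0))
        assert rmask.shape == (40, 40, 40)
        assert rmask.sum() >= 8

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            preprocess_map(np.ones((5, 5, 5)), np.zeros((5, 5, 5), bool),
                           DiscretizationPolicy.for_range(0, 1))


class TestExtract:
    def test_exactly_107_named_finite_values(self, ellipsoid_mask, rng):
        vol = rng.uniform(0, 1, (20, 20, 20))
        disc, rmask, vals = preprocess_map(vol, ellipsoid_mask,
                                           DiscretizationPolicy.for_range(0, 1))
        rv = extract_features(disc, rmask, values=vals, source_map="OEF")
        assert rv.values.shape == (107,)
        assert rv.names == FEATURE_NAMES
        assert np.isfinite(rv.values).all()

    def test_uniform_cube_firstorder(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:10, 2:10, 2:10] = True
        disc, rmask, vals = preprocess_map(np.full((12, 12, 12), 0.3), mask,
                                           DiscretizationPolicy.for_range(0, 1))
        d = extract_features(disc, rmask, values=vals, source_map="m").as_dict()
        assert d["m_firstorder_Mean"] == pytest.approx(0.3)
        assert d["m_firstorder_Variance"] == pytest.approx(0.0, abs=1e-18)
        assert d["m_firstorder_Uniformity"] == 1.0

    def test_checkerboard_has_higher_glcm_contrast_than_uniform(self, ellipsoid_mask):
        x, y, z = np.indices((20, 20, 20))
        cb = ((x + y + z) % 2).astype(float)
        pol = DiscretizationPolicy.for_range(0, 1)
        d_cb = extract_features(*preprocess_map(cb, ellipsoid_mask, pol)[:2],
                                source_map="m").as_dict()
        d_un = extract_features(*preprocess_map(np.full((20, 20, 20), 0.5),
                                                ellipsoid_mask, pol)[:2],
                                source_map="m").as_dict()
        assert d_cb["m_glcm_Contrast"] > d_un["m_glcm_Contrast"]

    def test_tiny_mask_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, :3] = True
        with pytest.raises(ValueError, match="8 voxels"):
            extract_features(np.ones((5, 5, 5), dtype=int), mask)

    def test_deterministic_for_fixed_input(self, ellipsoid_mask, rng):
        vol = rng.uniform(0, 1, (20, 20, 20))
        pol = DiscretizationPolicy.for_range(0, 1)
        a = extract_features(*preprocess_map(vol, ellipsoid_mask, pol)[:2], source_map="m")
        b = extract_features(*preprocess_map(vol, ellipsoid_mask, pol)[:2], source_map="m")
        assert np.array_equal(a.values, b.values)

    def test_shape_features_ignore_intensities(self, ellipsoid_mask, rng):
        pol = DiscretizationPolicy.for_range(0, 1)
        a = extract_features(*preprocess_map(rng.random((20, 20, 20)), ellipsoid_mask,
                                             pol)[:2], source_map="m")
        b = extract_features(*preprocess_map(rng.random((20, 20, 20)), ellipsoid_mask,
                                             pol)[:2], source_map="m")
        shape_slice = slice(0, 14)
        assert np.array_equal(a.values[shape_slice], b.values[shape_slice])

    def test_firstorder_invariant_to_affine_rescaling_under_zscore(self, ellipsoid_mask, rng):
        vol = rng.normal(100, 25, (20, 20, 20))
        pol = DiscretizationPolicy()
        norm = np.ones((20, 20, 20), bool)
        a = extract_features(*_pp(vol, ellipsoid_mask, pol, norm), source_map="m")
        b = extract_features(*_pp(3.0 * vol + 17.0, ellipsoid_mask, pol, norm), source_map="m")
        first = slice(14, 32)
        assert np.allclose(a.values[first], b.values[first], rtol=1e-9, atol=1e-9)


def _pp(vol, mask, pol, norm):
    disc, rmask, vals = preprocess_map(vol, mask, pol, norm_mask=norm)
    return disc, rmask, (1.0,) * 3, vals


class TestAssemble:
    def _vectors(self, maps, rng):
        mask = np.zeros((14, 14, 14), bool)
        mask[3:11, 3:11, 3:11] = True
        pol = DiscretizationPolicy.for_range(0, 1)
        out = {}
        for m in maps:
            disc, rmask, vals = preprocess_map(rng.random((14, 14, 14)), mask, pol)
            out[m] = extract_features(disc, rmask, values=vals, source_map=m)
        return out

    def test_four_maps_give_428(self, rng):
        vecs = self._vectors(CATEGORY_MAPS["oxymet"], rng)
        pv = assemble_vector(vecs, "oxymet")
        assert pv.values.shape == (428,)

    def test_combined_category_gives_856(self, rng):
        vecs = self._vectors(CATEGORY_MAPS["oxyvam"], rng)
        pv = assemble_vector(vecs, "oxyvam")
        assert pv.values.shape == (856,)
        assert pv.names[0].startswith("OEF_") and pv.names[-1].startswith("MTI_")

    def test_input_order_is_canonicalised(self, rng):
        vecs = self._vectors(CATEGORY_MAPS["oxymet"], rng)
        a = assemble_vector(vecs, "oxymet")
        shuffled = dict(reversed(list(vecs.items())))
        b = assemble_vector(shuffled, "oxymet")
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_missing_map_named_in_error(self, rng):
        vecs = self._vectors(("OEF", "CMRO2", "capiPO2"), rng)
        with pytest.raises(ValueError, match="mitoPO2"):
            assemble_vector(vecs, "oxymet")
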