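"""Region-level radiomics: family values vs hand/naive oracles, tables."""

import numpy as np
import pandas as pd
import pytest

from habitatrx.habitats import HabitatMap
from habitatrx.image import VolumePair
from habitatrx.regionfeat import (
    NGTDM_COARSENESS_CAP,
    RegionTooSmallError,
    build_feature_tables,
    extract_region_features,
    first_order_region,
    glrlm_region,
    region_feature_names,
    shape3d_region,
)
from habitatrx.synthetic import generate_phantom
from habitatrx.voxelfeat import directions_3d
from conftest import small_phantom_spec


def _pair_from_arrays(t2, adc, mask, spacing=(1.0, 1.0, 1.0)):
    return VolumePair(t2=t2, adc=adc, spacing=spacing, lesion_mask=mask,
                      patient_id="T")


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        feats = shape3d_region(mask, (1.0, 1.0, 1.0))
        assert feats["volume"] == pytest.approx(1.0)
        assert feats["surface_area"] == pytest.approx(6.0)
        assert feats["max_diameter"] == 0.0

    def test_volume_equals_count_times_voxel_volume(self, small_pair):
        pair, _ = small_pair
        feats = extract_region_features(pair, pair.lesion_mask)
        expected = pair.lesion_mask.sum() * np.prod(pair.spacing)
        assert feats[("shape", "shape3D", "volume")] == pytest.approx(expected)

    def test_cube_shape_descriptors(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True  # 4x4x4 cube
        feats = shape3d_region(mask, (1.0, 1.0, 1.0))
        assert feats["volume"] == pytest.approx(64.0)
        assert feats["surface_area"] == pytest.approx(6 * 16.0)
        # cube is isotropic: elongation and flatness ~ 1
        assert feats["elongation"] == pytest.approx(1.0, abs=1e-9)
        assert feats["flatness"] == pytest.approx(1.0, abs=1e-9)


class TestDegenerateRegions:
    def test_constant_region_conventions(self):
        mask = np.zeros((6, 6, 4), bool)
        mask[1:5, 1:5, 1:3] = True
        vol = np.full(mask.shape, 7.0)
        feats = extract_region_features(_pair_from_arrays(vol, vol, mask),
                                        mask)
        assert feats[("T2", "firstorder", "entropy")] == 0.0
        assert feats[("T2", "glcm", "maximum_probability")] == 1.0
        assert feats[("ADC", "ngtdm", "coarseness")] == NGTDM_COARSENESS_CAP
        assert all(np.isfinite(v) for v in feats.values())

    def test_region_too_small(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        vol = np.ones(mask.shape)
        with pytest.raises(RegionTooSmallError):
            extract_region_features(
                _pair_from_arrays(vol, vol, mask), mask, min_region_voxels=5
            )


def naive_glrlm(levels, n_bins):
    """Independent run-length enumeration over the 13 directions."""
    runs = {}
    shape = levels.shape
    for d in directions_3d():
        seen = set()
        for start in np.argwhere(levels > 0):
            start = tuple(start)
            prev = tuple(np.array(start) - d)
            inside = all(0 <= p < s for p, s in zip(prev, shape))
            if inside and levels[prev] == levels[start]:
                continue
            g = levels[start]
            length = 0
            pos = np.array(start)
            while (all(0 <= p < s for p, s in zip(pos, shape))
                   and levels[tuple(pos)] == g):
                length += 1
                pos += d
            runs[(tuple(d), start)] = (g, length)
    mat = {}
    for g, length in runs.values():
        mat[(g, length)] = mat.get((g, length), 0) + 1
    return mat


class TestGlrlm:
    def test_matches_naive_enumeration(self, rng):
        levels = rng.integers(1, 4, (3, 3, 3))
        stats = glrlm_region(levels, 4)
        naive = naive_glrlm(levels, 4)
        n_runs = sum(naive.values())
        sre = sum(c / length ** 2 for (g, length), c in naive.items()) / n_runs
        lre = sum(c * length ** 2 for (g, length), c in naive.items()) / n_runs
        hglre = sum(c * g ** 2 for (g, length), c in naive.items()) / n_runs
        assert stats["sre"] == pytest.approx(sre, rel=1e-12)
        assert stats["lre"] == pytest.approx(lre, rel=1e-12)
        assert stats["hglre"] == pytest.approx(hglre, rel=1e-12)

    def test_single_long_run(self):
        levels = np.zeros((5, 1, 1), dtype=np.int64)
        levels[:, 0, 0] = 2
        stats = glrlm_region(levels, 4)
        # along the run axis: one run of length 5; the other 12 directions
        # each contribute 5 runs of length 1
        assert stats["lre"] == pytest.approx((25 + 60) / 61)


class TestFirstOrder:
    def test_mean_matches_masked_average(self, small_pair):
        pair, _ = small_pair
        feats = extract_region_features(pair, pair.lesion_mask)
        assert feats[("T2", "firstorder", "mean")] == pytest.approx(
            pair.t2[pair.lesion_mask].mean(), rel=1e-12
        )
        assert feats[("ADC", "firstorder", "mean")] == pytest.approx(
            pair.adc[pair.lesion_mask].mean(), rel=1e-12
        )

    def test_named_statistics(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 10.0])
        f = first_order_region(vals)
        assert f["median"] == 2.0
        assert f["range"] == 9.0
        assert f["rms"] == pytest.approx(np.sqrt(np.mean(vals ** 2)))
        assert f["energy"] == pytest.approx(np.sum(vals ** 2))


class TestRotationalInvariance:
    def test_z_rotation_changes_texture_little(self):
        pair, _ = generate_phantom(small_phantom_spec(), 9)
        feats = extract_region_features(pair, pair.lesion_mask)
        rot = VolumePair(
            t2=np.rot90(pair.t2, axes=(0, 1)).copy(),
            adc=np.rot90(pair.adc, axes=(0, 1)).copy(),
            spacing=pair.spacing,
            lesion_mask=np.rot90(pair.lesion_mask, axes=(0, 1)).copy(),
            patient_id="rot",
        )
        feats_r = extract_region_features(rot, rot.lesion_mask)
        for key in feats:
            modality, family, _ = key
            if family in ("shape3D", "shape2D"):
                continue
            a, b = feats[key], feats_r[key]
            scale = max(abs(a), abs(b), 1e-9)
            assert abs(a - b) / scale < 0.05, key


@pytest.fixture(scope="module")
def toy_cohort():
    pairs, maps = [], []
    for i in range(3):
        pair, truth = generate_phantom(small_phantom_spec(), 20 + i,
                                       patient_id=f"P{i:04d}")
        props = np.array([(truth.habitat_labels == h).mean() for h in (1, 2, 3)])
        pairs.append(pair)
        maps.append(HabitatMap(labels=truth.habitat_labels,
                               proportions=props / props.sum(),
                               patient_id=pair.patient_id))
    return pairs, maps


class TestFeatureTables:

    def test_column_arithmetic(self, toy_cohort):
        pairs, maps = toy_cohort
        whole, habitat = build_feature_tables(pairs, maps)
        per_region = len(region_feature_names())
        assert whole.frame.shape[1] == per_region
        assert habitat.frame.shape[1] == 3 * per_region
        assert whole.frame.columns.is_unique and habitat.frame.columns.is_unique

    def test_missing_habitat_flagged_and_imputed(self, toy_cohort):
        pairs, maps = toy_cohort
        # erase habitat 2 from one patient
        erased = HabitatMap(
            labels=np.where(maps[0].labels == 2, 1, maps[0].labels),
            proportions=maps[0].proportions, patient_id=maps[0].patient_id,
        )
        whole, habitat = build_feature_tables(pairs, [erased] + maps[1:])
        pid = pairs[0].patient_id
        assert (pid, "hab2") in habitat.missing
        assert habitat.frame.loc[pid].isna().any()
        filled = habitat.impute_training_median(
            [p.patient_id for p in pairs[1:]]
        )
        assert not filled.frame.isna().any().any()

    def test_tables_reproducible(self, toy_cohort):
        pairs, maps = toy_cohort
        a = build_feature_tables(pairs, maps)[1].frame
        b = build_feature_tables(pairs, maps)[1].frame
        pd.testing.assert_frame_equal(a, b)

    def test_manifest_tags(self, toy_cohort):
        pairs, maps = toy_cohort
        whole, habitat = build_feature_tables(pairs, maps)
        entry = habitat.manifest["hab1_ADC_glcm_contrast"]
        assert entry["region"] == "hab1"
        assert entry["modality"] == "ADC"
        assert entry["family"] == "glcm"

    def test_extractor_hook(self, toy_cohort):
        pairs, maps = toy_cohort
        calls = []

        def fake(pair, mask):
            calls.append(pair.patient_id)
            return {("T2", "firstorder", "mean"): 1.0}

        whole, habitat = build_feature_tables(pairs, maps, extractor=fake)
        assert whole.frame.shape == (3, 1)
        assert len(calls) == 3 * 4  # whole + 3 habitats per patient
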