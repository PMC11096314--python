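"""Calcium-omics features: scores, shape, statistics, distances, registry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calciomics.features import (
    agatston_weight, build_feature_vector, default_registry, hu_histogram,
    hu_statistics, lesion_agatston, lesion_mass, lesion_shape,
    sequential_distances, territory_diffusivity, territory_features,
)
from calciomics.lesions import extract_lesions
from calciomics.phantoms import LesionSpec, PhantomSpec, make_phantom
from calciomics.volumes import CTVolume, TerritoryMask, TERRITORY_NAMES

from conftest import brute_force_agatston, random_phantom_pair


def _lesion_from(data, spacing=(0.5, 0.5, 2.5)):
    vol = CTVolume(data=np.asarray(data, dtype=float), spacing=spacing)
    mask = TerritoryMask(labels=np.full(vol.shape, 2, dtype=np.int16))
    table = extract_lesions(vol, mask, min_voxels=1)
    assert len(table) == 1
    return table.lesions[0]


class TestAgatston:
    @pytest.mark.parametrize("hu,expected", [
        (130, 1), (199, 1), (200, 2), (299, 2), (300, 3), (399, 3),
        (400, 4), (1500, 4),
    ])
    def test_weight_bins(self, hu, expected):
        assert agatston_weight(hu) == expected

    def test_weight_below_130_is_contract_violation(self):
        with pytest.raises(ValueError):
            agatston_weight(129.9)

    def test_single_slice_eight_voxels(self):
        # 8 voxels at 0.5x0.5 mm = 2.0 mm2, slice max 320 -> weight 3 -> 6.0
        data = np.zeros((1, 4, 4))
        data[0, 1, 0:4] = 320.0
        data[0, 2, 0:4] = 320.0
        assert lesion_agatston(_lesion_from(data)) == pytest.approx(6.0)

    def test_per_slice_additivity(self):
        # same 8 voxels split over two slices, both slice maxima 320
        data = np.zeros((2, 4, 4))
        data[0, 1, 0:4] = 320.0
        data[1, 1, 0:4] = 320.0
        assert lesion_agatston(_lesion_from(data)) == pytest.approx(6.0)

    def test_three_voxels_at_exactly_130(self):
        data = np.zeros((1, 4, 4))
        data[0, 1, 0:3] = 130.0
        assert lesion_agatston(_lesion_from(data)) == pytest.approx(0.75)


class TestMass:
    def test_direct_product(self):
        data = np.zeros((1, 4, 8))
        data[0, 1, 0:8] = 300.0   # 8 voxels x 0.625 mm3 = 5 mm3, mean HU 300
        lesion = _lesion_from(data)
        assert lesion.volume_mm3 == pytest.approx(5.0)
        assert lesion_mass(lesion, calibration_c=0.001) == pytest.approx(1.5)

    def test_zero_calibration(self):
        data = np.zeros((1, 4, 4))
        data[0, 1, 0:3] = 300.0
        assert lesion_mass(_lesion_from(data), calibration_c=0.0) == 0.0

    def test_linearity_in_volume(self):
        d1 = np.zeros((1, 4, 8)); d1[0, 1, 0:4] = 300.0
        d2 = np.zeros((1, 4, 8)); d2[0, 1, 0:8] = 300.0
        assert lesion_mass(_lesion_from(d2)) == pytest.approx(2 * lesion_mass(_lesion_from(d1)))


class TestShape:
    def test_collinear_voxels_hit_floor_and_stay_finite(self):
        data = np.zeros((1, 4, 8))
        data[0, 1, 0:3] = 200.0
        sph, elo = lesion_shape(_lesion_from(data), (0.5, 0.5, 2.5))
        assert np.isfinite(sph) and np.isfinite(elo) and elo >= 1.0

    def test_large_ball_sphericity_matches_brute_force_surface_count(self):
        # Exposed-face surface counting over-estimates a smooth sphere's
        # area by a staircase factor approaching 3/2, so the voxel
        # sphericity of a large rasterized ball approaches 2/3, not 1.
        spec = PhantomSpec(shape=(40, 60, 60), spacing=(1.0, 1.0, 1.0), lesions=(
            LesionSpec("LAD", (30.0, 30.0, 20.0), (14.0, 14.0, 14.0), 300.0),))
        vol, mask, _ = make_phantom(spec)
        lesion = extract_lesions(vol, mask).lesions[0]
        sph, _ = lesion_shape(lesion, vol.spacing)
        voxset = {tuple(v) for v in lesion.voxel_indices}
        faces = 0
        for (i, j, k) in voxset:
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                if (i + d[0], j + d[1], k + d[2]) not in voxset:
                    faces += 1
        expected = np.pi ** (1 / 3) * (6 * lesion.volume_mm3) ** (2 / 3) / faces
        assert sph == pytest.approx(expected, rel=1e-9)
        assert sph == pytest.approx(2.0 / 3.0, rel=0.10)
        assert sph < 1.0

    def test_rod_elongation_increases_with_length(self):
        prev = 0.0
        for n in (4, 8, 16):
            data = np.zeros((1, 4, 20))
            data[0, 1, 0:n] = 200.0
            _, elo = lesion_shape(_lesion_from(data, spacing=(1.0, 1.0, 1.0)), (1.0, 1.0, 1.0))
            # closed-form variance of a uniform line of n unit-spaced points
            expected = np.sqrt((n * n - 1) / 12.0 / 0.25)
            assert elo == pytest.approx(expected, rel=1e-6)
            assert elo > prev
            prev = elo


class TestHUStatistics:
    def test_constant_sample(self):
        assert hu_statistics([200, 200, 200]) == (200.0, 0.0, 0.0, 0.0)

    def test_hand_moment_computation(self):
        vals = np.array([130.0, 200.0, 470.0])
        mean, sd, skew, kurt = hu_statistics(vals)
        m = vals.mean()
        m2 = ((vals - m) ** 2).mean()
        m3 = ((vals - m) ** 3).mean()
        assert mean == pytest.approx(266.66667, abs=1e-4)
        assert sd == pytest.approx(np.sqrt(m2))
        assert skew == pytest.approx(m3 / m2 ** 1.5)
        assert kurt == 0.0   # n < 4 convention

    def test_symmetric_sample_has_zero_skewness(self):
        m = 300.0
        a, b = 150.0, 250.0
        _, _, skew, _ = hu_statistics([a, b, 2 * m - b, 2 * m - a])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hu_statistics([])


class TestHUHistogram:
    def test_edge_inclusion(self):
        assert tuple(hu_histogram([130, 199])) == (2, 0, 0, 0, 0)

    def test_bin_by_bin_assignment(self):
        assert tuple(hu_histogram([200, 300, 400, 1000])) == (0, 1, 1, 1, 1)

    def test_empty(self):
        assert tuple(hu_histogram([])) == (0, 0, 0, 0, 0)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(130, 2000, 50)
        assert hu_histogram(vals).sum() == 50


class TestSequentialDistances:
    def _lesions_at(self, centroids):
        from calciomics.lesions import Lesion
        return [
            Lesion(lesion_id=i + 1, territory="LAD",
                   voxel_indices=np.zeros((3, 3), dtype=int),
                   hu_values=np.full(3, 200.0), volume_mm3=1.0,
                   centroid_mm=tuple(c), per_slice_areas=((0, 1.0, 200.0),))
            for i, c in enumerate(centroids)
        ]

    def test_collinear_chain(self):
        lesions = self._lesions_at([(0, 0, 0), (0, 0, 5), (0, 0, 10)])
        d_next, d_f2l, d_t2l = sequential_distances(lesions)
        assert d_next[:2] == [5.0, 5.0] and d_next[2] is None
        assert d_f2l == pytest.approx(10.0)
        assert d_t2l == pytest.approx(10.0)

    def test_single_lesion_boundary(self):
        lesions = self._lesions_at([(3.0, 4.0, 12.0)])
        d_next, d_f2l, d_t2l = sequential_distances(lesions)
        assert d_next == [None]
        assert d_f2l == 0.0
        assert d_t2l == pytest.approx(12.0)   # equals dist_to_top of the lesion

    def test_top_conventions(self):
        lesions = self._lesions_at([(3.0, 0.0, 5.0), (7.0, 0.0, 10.0)])
        _, _, d_offset = sequential_distances(lesions, top_convention="offset")
        _, _, d_z = sequential_distances(lesions, top_convention="z")
        assert d_offset == pytest.approx(np.sqrt(16.0 + 100.0))
        assert d_z == pytest.approx(10.0)


class TestDiffusivity:
    def test_empty_territory_convention(self):
        assert territory_diffusivity(0, 0.0) == 0.0

    def test_single_lesion_convention(self):
        assert territory_diffusivity(1, 0.0) == 1.0

    def test_direct_ratio(self):
        assert territory_diffusivity(4, 20.0) == pytest.approx(0.2)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            territory_diffusivity(2, 0.0)


class TestFeatureVector:
    def test_exactly_80_entries_in_registry_order(self, multi_lesion_phantom):
        vol, mask, _ = multi_lesion_phantom
        vec = build_feature_vector(extract_lesions(vol, mask))
        registry = default_registry()
        assert len(vec) == 80
        assert list(vec) == list(registry.names)

    def test_zero_calcium_patient_is_all_zero(self, zero_calcium_phantom):
        vol, mask, _ = zero_calcium_phantom
        vec = build_feature_vector(extract_lesions(vol, mask))
        assert all(v == 0.0 for v in vec.values())

    def test_phantom_ground_truth_recovered_exactly(self, multi_lesion_phantom):
        vol, mask, truth = multi_lesion_phantom
        vec = build_feature_vector(extract_lesions(vol, mask))
        assert vec["Agatston"] == pytest.approx(truth["total_agatston"])
        assert vec["MassScore"] == pytest.approx(truth["total_mass_mg"])
        assert vec["VolumeScore"] == pytest.approx(truth["total_volume_mm3"])
        assert vec["NumLesions"] == truth["num_lesions"]

    def test_whole_heart_additivity_over_territories_and_lesions(self, multi_lesion_phantom):
        vol, mask, _ = multi_lesion_phantom
        table = extract_lesions(vol, mask)
        vec = build_feature_vector(table)
        for whole, per in [("Agatston", "Agatston"), ("MassScore", "Mass"),
                           ("VolumeScore", "Volume"), ("NumLesions", "NumLesions")]:
            assert vec[whole] == pytest.approx(
                sum(vec[f"{per}_{t}"] for t in TERRITORY_NAMES))
        assert vec["Agatston"] == pytest.approx(
            sum(lesion_agatston(l) for l in table.lesions))

    def test_translation_invariance_except_top_distance(self):
        def _vec(z_shift_slices):
            data = np.zeros((12, 16, 16))
            data[2 + z_shift_slices:4 + z_shift_slices, 4:7, 4:7] = 300.0
            data[6 + z_shift_slices:8 + z_shift_slices, 10:12, 10:12] = 500.0
            vol = CTVolume(data=data, spacing=(0.5, 0.5, 2.5))
            mask = TerritoryMask(labels=np.full(data.shape, 2, dtype=np.int16))
            return build_feature_vector(extract_lesions(vol, mask))
        v0, v1 = _vec(0), _vec(2)
        for name in v0:
            if "DistTop2LastLesion" in name:
                if v0["NumLesions_" + name.split("_")[-1]] > 0:
                    assert v1[name] > v0[name]   # moves away from the top
            else:
                assert v1[name] == pytest.approx(v0[name]), name

    @pytest.mark.parametrize("seed", range(5))
    def test_scores_match_brute_force_on_random_phantoms(self, seed):
        vol, mask = random_phantom_pair(seed)
        table = extract_lesions(vol, mask)
        for lesion in table.lesions:
            vox = [tuple(v) for v in lesion.voxel_indices]
            hu = {tuple(v): h for v, h in zip(lesion.voxel_indices, lesion.hu_values)}
            expected = brute_force_agatston(vox, [hu[v] for v in vox], vol.spacing)
            # brute_force_agatston indexes hu positionally
            expected = brute_force_agatston(vox, list(lesion.hu_values), vol.spacing)
            assert lesion_agatston(lesion) == pytest.approx(expected)
            assert lesion_mass(lesion) == pytest.approx(
                0.001 * np.mean(list(lesion.hu_values)) * len(vox) * vol.voxel_volume_mm3)

    def test_missing_registry_name_raises_schema_error(self, multi_lesion_phantom):
        from calciomics.features import FeatureRegistry
        vol, mask, _ = multi_lesion_phantom
        bad = FeatureRegistry(version="x", names=("Agatston", "NotAFeature"))
        with pytest.raises(KeyError, match="NotAFeature"):
            build_feature_vector(extract_lesions(vol, mask), registry=bad)


class TestProperties:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=130.0, max_value=5000.0,
                              allow_nan=False), max_size=60))
    def test_histogram_counts_always_sum_to_sample_size(self, vals):
        assert hu_histogram(vals).sum() == len(vals)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(min_value=130.0, max_value=10000.0, allow_nan=False),
           st.floats(min_value=130.0, max_value=10000.0, allow_nan=False))
    def test_agatston_weight_monotone_in_density(self, a, b):
        wa, wb = agatston_weight(a), agatston_weight(b)
        assert wa in (1, 2, 3, 4) and wb in (1, 2, 3, 4)
        if a <= b:
            assert wa <= wb

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=2, max_value=100),
           st.floats(min_value=0.1, max_value=500.0, allow_nan=False))
    def test_diffusivity_is_the_plain_ratio_beyond_one_lesion(self, n, dist):
        assert territory_diffusivity(n, dist) == pytest.approx(n / dist)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(min_value=130.0, max_value=3000.0,
                              allow_nan=False), min_size=1, max_size=40))
    def test_hu_statistics_match_numpy_population_moments(self, vals):
        mean, sd, _, _ = hu_statistics(vals)
        assert mean == pytest.approx(np.mean(vals))
        assert sd == pytest.approx(np.std(vals))


class TestScaleBehavior:
    def test_spacing_scale_laws(self):
        def _vec(scale):
            data = np.zeros((10, 12, 12))
            data[2:4, 4:7, 4:7] = 300.0
            data[6:8, 8:10, 8:10] = 500.0
            vol = CTVolume(data=data, spacing=(0.5 * scale, 0.5 * scale, 2.5 * scale))
            mask = TerritoryMask(labels=np.full(data.shape, 2, dtype=np.int16))
            return build_feature_vector(extract_lesions(vol, mask))
        v1, v2 = _vec(1.0), _vec(2.0)
        s = 2.0
        assert v2["VolumeScore"] == pytest.approx(s ** 3 * v1["VolumeScore"])
        assert v2["Agatston"] == pytest.approx(s ** 2 * v1["Agatston"])
        assert v2["DistFirst2LastLesionPerArtery_LAD"] == pytest.approx(
            s * v1["DistFirst2LastLesionPerArtery_LAD"])
        assert v2["Diffusivity_LAD"] == pytest.approx(v1["Diffusivity_LAD"] / s)

    def test_diffusivity_denominator_dialects(self, multi_lesion_phantom):
        vol, mask, _ = multi_lesion_phantom
        table = extract_lesions(vol, mask)
        path = territory_features(table, "LAD", diffusivity_denominator="path")
        chord = territory_features(table, "LAD", diffusivity_denominator="chord")
        assert path["NumLesions"] == 2
        # with exactly two lesions, path and chord coincide
        assert path["Diffusivity"] == pytest.approx(chord["Diffusivity"])
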