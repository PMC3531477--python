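import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from centrotrace.quantify import (
    CentromereMeasurement,
    EmptyCellError,
    SegmentationParams,
    SpotRegion,
    assign_chromosomes,
    cell_total,
    compare_groups,
    corrected_intensity,
    identify_intensity_outlier,
    measurements_frame,
    normalize_to_control,
    normalize_within_cell,
    segment_spots,
)
from centrotrace.synthetic import Landmark, SceneConfig, generate_scene

from conftest import nearest_region


class TestCorrectedIntensity:
    def test_pure_background_vanishes(self):
        # uniform background b=5 in both regions must correct to exactly 0
        region = SpotRegion(10, 50.0, 20, 100.0)
        assert corrected_intensity(region) == 0.0

    def test_hand_arithmetic(self):
        region = SpotRegion(10, 150.0, 20, 200.0)
        assert corrected_intensity(region) == pytest.approx(100.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpotRegion(20, 50.0, 20, 100.0)  # A_l == A_s
        with pytest.raises(ValueError):
            SpotRegion(0, 0.0, 5, 10.0)  # A_s == 0
        with pytest.raises(ValueError):
            SpotRegion(5, 100.0, 10, 50.0)  # I_l < I_s

    def test_negative_value_reported_with_warning(self):
        # ring brighter than the spot: corrected goes negative, not clamped
        region = SpotRegion(10, 100.0, 20, 400.0)
        with pytest.warns(UserWarning):
            value = corrected_intensity(region)
        assert value == pytest.approx(100.0 - 10 * 300.0 / 10.0)
        assert value < 0

    @settings(max_examples=200, deadline=None)
    @given(
        a_s=st.integers(1, 500),
        extra=st.integers(1, 500),
        base=st.floats(0.0, 1e4),
        signal=st.floats(0.0, 1e6),
        c=st.floats(-1e3, 1e3),
    )
    def test_background_invariance(self, a_s, extra, base, signal, c):
        # adding a constant c per pixel leaves the corrected value unchanged
        a_l = a_s + extra
        i_s = base * a_s + signal
        i_l = base * a_l + signal
        v0 = i_s - a_s * (i_l - i_s) / (a_l - a_s)
        i_s2 = i_s + c * a_s
        i_l2 = i_l + c * a_l
        v1 = i_s2 - a_s * (i_l2 - i_s2) / (a_l - a_s)
        assert v1 == pytest.approx(v0, rel=1e-9, abs=1e-4)


class TestSegmentSpots:
    def test_single_spot_noise_free(self):
        cfg = SceneConfig(
            stage="wing_disc", n_nuclei=1, image_size=(128, 128),
            noise_sd=0.0, diffuse_nuclear_level=0.0, seed=1,
        )
        scene = generate_scene(cfg)
        regions = segment_spots(scene.gfp_image)
        assert len(regions) == 1
        assert math.dist(regions[0].centroid, scene.spots[0].center) < 2.0

    def test_flat_image_empty(self):
        assert segment_spots(np.full((128, 128), 7.0)) == []

    def test_region_invariant_holds(self, s5_batch):
        for _, regions in s5_batch[:5]:
            for r in regions:
                assert r.area_enlarged > r.area_selected > 0
                assert r.intensity_enlarged >= r.intensity_selected >= 0

    def test_s5_seven_regions_per_nucleus(self, s5_batch):
        # ground-truth oracle: each S5 nucleus renders 7 spots; segmentation
        # must find exactly 7 in >= 95% of 100 seeded nuclei
        good = total = 0
        for scene, regions in s5_batch:
            counts = Counter(r.nucleus_id for r in regions)
            for nid in np.unique(scene.nucleus_masks)[1:]:
                total += 1
                good += counts.get(int(nid), 0) == 7
        assert total == 100
        assert good / total >= 0.95

    def test_noise_free_recovery_within_1pct(self):
        errs = []
        for seed in range(3):
            cfg = SceneConfig(
                stage="wing_disc", n_nuclei=12, noise_sd=0.0, diffuse_nuclear_level=0.0, seed=seed
            )
            scene = generate_scene(cfg)
            regions = segment_spots(scene.gfp_image, nucleus_labels=scene.nucleus_masks)
            for s in scene.spots:
                r = regions[nearest_region(regions, s.center)]
                errs.append(abs(corrected_intensity(r) / s.true_signal - 1))
        assert len(errs) >= 30
        assert max(errs) < 0.01

    def test_default_noise_recovery_within_5pct_median(self, s5_batch):
        errs = []
        for scene, regions in s5_batch:
            for s in scene.spots:
                r = regions[nearest_region(regions, s.center)]
                errs.append(abs(corrected_intensity(r) / s.true_signal - 1))
        assert len(errs) >= 100
        assert np.median(errs) < 0.05


class TestCellTotal:
    def _measurements(self, values, nid=1):
        return [CentromereMeasurement(v, nucleus_id=nid) for v in values]

    def test_arithmetic(self):
        cell = cell_total(self._measurements([40.0, 60.0]), 1, ploidy=4)
        assert cell.total_corrected_intensity == pytest.approx(100.0)
        assert cell.per_genome_intensity == pytest.approx(25.0)

    def test_single_spot_identity(self):
        cell = cell_total(self._measurements([123.4]), 1, ploidy=1)
        assert cell.total_corrected_intensity == pytest.approx(123.4)

    def test_ploidy_identity(self):
        cell = cell_total(self._measurements([40.0, 60.0, 30.0]), 1, ploidy=4)
        assert cell.per_genome_intensity * cell.ploidy == pytest.approx(
            cell.total_corrected_intensity
        )

    def test_spermatocyte_vs_spermatid_ratio(self):
        # equal per-genome levels at ploidy 4 vs 1 give totals in ratio 4:1
        per_genome = 25.0
        s46 = cell_total(self._measurements([per_genome * 4]), 1, ploidy=4)
        tid = cell_total(self._measurements([per_genome]), 1, ploidy=1)
        assert s46.per_genome_intensity == pytest.approx(tid.per_genome_intensity)
        assert s46.total_corrected_intensity / tid.total_corrected_intensity == pytest.approx(4.0)

    def test_unknown_nucleus(self):
        with pytest.raises(KeyError):
            cell_total(self._measurements([1.0]), 99)


class TestNormalization:
    def test_within_cell_symmetry(self):
        assert normalize_within_cell([25, 25, 25, 25]) == pytest.approx([25, 25, 25, 25])

    def test_within_cell_arithmetic(self):
        assert normalize_within_cell([2, 1, 1]) == pytest.approx([50, 25, 25])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(1e-3, 1e6), min_size=1, max_size=12))
    def test_within_cell_sums_exactly_100(self, values):
        assert normalize_within_cell(values).sum() == 100.0

    def test_within_cell_empty_total(self):
        with pytest.raises(EmptyCellError):
            normalize_within_cell([0.0, 0.0])

    def test_to_control_arithmetic(self):
        assert normalize_to_control([10.0], [10.0, 30.0]) == pytest.approx([50.0])

    def test_control_maps_to_100(self):
        control = [10.0, 30.0, 50.0]
        assert normalize_to_control(control, control).mean() == pytest.approx(100.0)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [])


class TestAssignChromosomes:
    def test_matches_ground_truth(self, s5_batch):
        ok = total = 0
        for scene, regions in s5_batch:
            classes = assign_chromosomes(regions, scene.dna_image, scene.landmarks_frame())
            for s in scene.spots:
                total += 1
                ok += classes[nearest_region(regions, s.center)] == s.chromosome_class
        assert total >= 100
        assert ok / total >= 0.95

    def test_no_landmarks_all_unassigned(self, s5_batch):
        scene, regions = s5_batch[0]
        classes = assign_chromosomes(regions, scene.dna_image, [])
        assert set(classes) == {"unassigned"}

    def test_merged_x_pair4_excluded(self):
        # both landmarks point at the same region: exclusion, not a guess
        merged = SpotRegion(10, 500.0, 30, 520.0, nucleus_id=1, centroid=(10.0, 10.0))
        other = SpotRegion(10, 300.0, 30, 320.0, nucleus_id=1, centroid=(40.0, 40.0))
        landmarks = [
            Landmark(1, "bright_dot_chr4", (11.0, 10.0)),
            Landmark(1, "irregular_X_region", (9.0, 10.0)),
        ]
        classes = assign_chromosomes([merged, other], None, landmarks)
        assert classes[0] == "unassigned"

    def test_tie_broken_by_intensity(self):
        bright = SpotRegion(10, 900.0, 30, 920.0, nucleus_id=1, centroid=(10.0, 6.0))
        dim = SpotRegion(10, 300.0, 30, 320.0, nucleus_id=1, centroid=(10.0, 14.0))
        landmarks = [Landmark(1, "bright_dot_chr4", (10.0, 10.0))]
        classes = assign_chromosomes([bright, dim], None, landmarks)
        assert classes[0] == "pair4"
        assert classes[1] != "pair4"

    def test_distance_cap(self):
        far = SpotRegion(10, 500.0, 30, 520.0, nucleus_id=1, centroid=(100.0, 100.0))
        landmarks = [Landmark(1, "bright_dot_chr4", (10.0, 10.0))]
        assert assign_chromosomes([far], None, landmarks) == ["unassigned"]


class TestOutlier:
    def test_forced_outlier(self):
        assert identify_intensity_outlier([1, 1, 1, 2.2], 1.5) == 3

    def test_no_outlier(self):
        assert identify_intensity_outlier([1, 1, 1, 1], 1.5) is None

    def test_twofold_y_signal_detected(self):
        values = [1.0] * 7 + [2.0]
        assert identify_intensity_outlier(values, 1.5) == 7

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            identify_intensity_outlier([1.0, 2.0], 1.5)

    def test_rule_equivalence_exhaustive(self):
        # brute-force oracle over all permutations of <= 8 values
        def oracle(values, threshold):
            best_i, best_v = max(enumerate(values), key=lambda kv: kv[1])
            rest = sorted(v for j, v in enumerate(values) if j != best_i)
            n = len(rest)
            med = (rest[(n - 1) // 2] + rest[n // 2]) / 2.0
            return best_i if best_v > threshold * med else None

        for base in ([1, 1, 1, 2.0], [1, 2, 3, 4, 5], [1.0, 1.0, 1.4], [2, 2, 2, 2, 4, 1, 1, 1]):
            for perm in itertools.permutations(base):
                assert identify_intensity_outlier(list(perm), 1.5) == oracle(list(perm), 1.5)


class TestCompareGroups:
    def test_identical_groups(self):
        result = compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert result["fold_change"] == pytest.approx(1.0)
        assert result["p_value"] == 1.0

    def test_closed_form_welch_oracle(self):
        a = [10.0, 10.0, 10.0, 10.0]
        b = [20.0, 20.0, 20.0, 21.0]
        result = compare_groups(a, b)
        assert result["fold_change"] == pytest.approx(20.25 / 10.0)
        # independent oracle: Welch t statistic and df computed by hand
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        na, nb = len(a), len(b)
        se2 = va / na + vb / nb
        t = (mb - ma) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert result["p_value"] == pytest.approx(p, rel=1e-9)
        assert result["p_value"] < 0.001

    def test_large_separation_rejected(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(25):
            a = rng.normal(100.0, 5.0, 20)
            b = rng.normal(200.0, 5.0, 20)
            rejections += compare_groups(a, b)["p_value"] < 0.001
        assert rejections == 25

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


def test_measurements_frame_columns(s5_batch):
    scene, regions = s5_batch[0]
    classes = assign_chromosomes(regions, scene.dna_image, scene.landmarks_frame())
    frame = measurements_frame(regions, classes)
    assert list(frame.columns[:8]) == [
        "nucleus_id", "chromosome_class", "A_s", "I_s", "A_l", "I_l", "corrected", "negative",
    ]
    assert len(frame) == len(regions)
    assert (frame["corrected"] > 0).all()
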