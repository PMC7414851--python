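"""Nucleus segmentation, focus detection/counting, registration, overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import replimap as rm
from replimap.pla import transform_points


def _render_disks(shape, centres, radius, intensity=200.0, noise_sd=2.0,
                  seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for cy, cx in centres:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] = intensity
    return img + rng.normal(0, noise_sd, shape)


def _render_spots(shape, points, amplitude=60.0, sigma=1.5, noise_sd=2.0,
                  seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = rng.normal(0, noise_sd, shape)
    for cy, cx in points:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                  / (2 * sigma ** 2))
    return img


class TestSegmentNuclei:
    def test_three_separated_disks(self):
        centres = [(40, 40), (40, 120), (120, 80)]
        img = _render_disks((160, 160), centres, radius=15)
        seg = rm.segment_nuclei(img, min_area=200)
        assert seg.n_nuclei == 3
        got = seg.records[["cy", "cx"]].to_numpy()
        for cy, cx in centres:
            d = np.sqrt(((got - [cy, cx]) ** 2).sum(axis=1)).min()
            assert d < 1.0

    def test_blank_image_gives_no_nuclei(self):
        rng = np.random.default_rng(1)
        seg = rm.segment_nuclei(rng.normal(0, 2, (128, 128)))
        assert seg.n_nuclei == 0

    def test_small_object_filtered(self):
        img = _render_disks((128, 128), [(64, 64)], radius=7)  # area ~150
        seg = rm.segment_nuclei(img, min_area=200)
        assert seg.n_nuclei == 0


class TestDetectFoci:
    def test_five_separated_spots(self):
        pts = [(20, 20), (20, 100), (60, 60), (100, 20), (100, 100)]
        img = _render_spots((128, 128), pts)
        foci = rm.detect_foci(img, max_area=50)
        assert len(foci) == 5
        got = foci[["cy", "cx"]].to_numpy()
        for p in pts:
            assert np.sqrt(((got - p) ** 2).sum(axis=1)).min() < 1.0

    def test_oversized_blob_rejected(self):
        img = _render_disks((128, 128), [(64, 64)], radius=10, intensity=60)
        foci = rm.detect_foci(img, max_area=50)
        assert len(foci) == 0

    def test_blank_image(self):
        rng = np.random.default_rng(2)
        foci = rm.detect_foci(rng.normal(0, 2, (128, 128)))
        assert len(foci) == 0


class TestAssignAndCount:
    def test_centroid_containment(self):
        img = _render_disks((128, 128), [(40, 40), (90, 90)], radius=15)
        seg = rm.segment_nuclei(img)
        foci = pd.DataFrame({"focus_id": [1, 2], "cy": [40.0, 5.0],
                             "cx": [42.0, 5.0], "area": [4, 4]})
        assigned = rm.assign_foci(foci, seg)
        inside = assigned[assigned["parent"] > 0]
        assert len(inside) == 1  # the focus outside all nuclei is excluded
        counts = rm.count_foci_per_nucleus(foci, seg)
        assert sorted(counts["count"]) == [0, 1]

    def test_counts_match_ground_truth(self, default_pla):
        """On resolvable synthetic fields every nucleus count is exact."""
        cfg, images, truth = default_pla
        for cond, stack in images.items():
            seg = rm.segment_nuclei(stack[0], min_area=200)
            foci = rm.detect_foci(stack[1], max_area=50)
            counts = rm.count_foci_per_nucleus(foci, seg)
            true_centres = np.array(truth.foci[cond]["centres"])
            true_counts = truth.foci[cond]["counts"]
            assert seg.n_nuclei == len(true_centres)
            rec = seg.records
            for k, (cy, cx) in enumerate(true_centres):
                d = ((rec["cy"] - cy) ** 2 + (rec["cx"] - cx) ** 2).to_numpy()
                nid = int(rec["nucleus_id"].iloc[d.argmin()])
                got = int(counts.loc[counts["nucleus_id"] == nid, "count"].iloc[0])
                assert got == true_counts[k]

    def test_no_double_counting(self, default_pla):
        _, images, _ = default_pla
        stack = images["early"]
        seg = rm.segment_nuclei(stack[0])
        foci = rm.detect_foci(stack[1])
        assigned = rm.assign_foci(foci, seg)
        counts = rm.count_foci_per_nucleus(foci, seg)
        assert counts["count"].sum() == (assigned["parent"] > 0).sum()


class TestCompareConditions:
    def test_constructed_fold_five(self):
        out = rm.compare_conditions([5] * 30, [1] * 30)
        assert out["fold_ratio"] == pytest.approx(5.0)
        assert out["p_value"] < 1e-3
        assert out["label"] == "significant"

    def test_identical_vectors(self):
        out = rm.compare_conditions([2, 3, 2, 3], [2, 3, 2, 3])
        assert out["fold_ratio"] == pytest.approx(1.0)
        assert out["label"] == "NS"

    def test_degenerate_all_equal(self):
        out = rm.compare_conditions([2, 2, 2], [2, 2, 2])
        assert out["p_value"] == 1.0

    def test_poisson_ratio_recovered(self, default_pla):
        """lambda 4 vs 1 with 60 nuclei per arm: estimated fold within
        Poisson sampling error of the true ratio 4."""
        _, images, _ = default_pla
        counts = {}
        for cond, stack in images.items():
            seg = rm.segment_nuclei(stack[0])
            foci = rm.detect_foci(stack[1])
            counts[cond] = rm.count_foci_per_nucleus(foci, seg)["count"]
        out = rm.compare_conditions(counts["early"], counts["late"],
                                    label_a="early", label_b="late")
        assert 3.0 <= out["fold_ratio"] <= 5.0
        assert out["p_value"] < 1e-3

    def test_null_p_values_uniform(self):
        """Equal lambda in both arms: comparison p-values are uniform
        (KS alpha = 0.01 over 200 seeds)."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.poisson(3.0, size=40)
            b = rng.poisson(3.0, size=40)
            ps.append(rm.compare_conditions(a, b)["p_value"])
        _, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01


@pytest.fixture(scope="module")
def dapi_field():
    cfg = rm.SimPlaConfig(seed=5, n_nuclei=15, image_shape=(256, 256),
                          lambda_by_condition={"x": 3.0})
    images, truth = rm.simulate_pla_images(cfg)
    return images["x"][0], truth


class TestRegistration:
    def test_identity(self, dapi_field):
        img, _ = dapi_field
        tr = rm.register_rounds(img, img)
        assert abs(tr.dy) < 0.1 and abs(tr.dx) < 0.1
        assert abs(tr.angle_deg) < 0.1
        assert tr.reliable

    @pytest.mark.parametrize("dy,dx,angle", [
        (3.0, 5.0, 0.0), (0.0, 0.0, 10.0), (-4.0, 2.0, -6.0),
        (2.5, -3.5, 4.0),
    ])
    def test_known_drift_recovered(self, dapi_field, dy, dx, angle):
        img, _ = dapi_field
        moved = rm.shift_and_rotate_stack(img, dy, dx, angle)
        tr = rm.register_rounds(img, moved)
        assert abs(tr.dy - dy) < 0.5
        assert abs(tr.dx - dx) < 0.5
        assert abs(tr.angle_deg - angle) < 0.5

    def test_unreliable_flagged(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(128, 128))
        b = rng.normal(size=(128, 128))
        tr = rm.register_rounds(a, b)
        assert not tr.reliable

    def test_transform_points_matches_image_transform(self):
        img = np.zeros((101, 101))
        img[30, 40] = 100.0
        tr = rm.RigidTransform(3, 5, 12)
        moved = rm.shift_and_rotate_stack(img, tr.dy, tr.dx, tr.angle_deg)
        landed = np.unravel_index(np.argmax(moved), moved.shape)
        pred = transform_points([[30, 40]], tr, (101, 101))[0]
        assert np.abs(pred - landed).max() < 1.0
        back = transform_points([pred], tr, (101, 101), inverse=True)[0]
        assert np.allclose(back, [30, 40], atol=1e-9)

    def test_drift_sanity_bound(self):
        with pytest.raises(ValueError, match="45"):
            rm.RigidTransform(0, 0, 50)


class TestOverlap:
    def _foci(self, pts):
        pts = np.asarray(pts, dtype=float)
        return pd.DataFrame({"focus_id": np.arange(1, len(pts) + 1),
                             "cy": pts[:, 0], "cx": pts[:, 1]})

    def test_identical_sets(self):
        f = self._foci([(10, 10), (30, 30), (50, 10)])
        frac, _ = rm.overlap_fraction(f, f.copy(), radius=2.0)
        assert frac == 1.0

    def test_far_separated_sets(self):
        f1 = self._foci([(10, 10), (20, 20)])
        f2 = self._foci([(100, 100), (120, 120)])
        frac, _ = rm.overlap_fraction(f1, f2, radius=2.0)
        assert frac == 0.0

    def test_empty_set(self):
        f1 = self._foci([(10, 10)])
        empty = pd.DataFrame(columns=["focus_id", "cy", "cx"])
        assert rm.overlap_fraction(f1, empty, radius=2.0) == (0.0, 1.0)

    def test_greedy_matching_is_one_to_one(self):
        f1 = self._foci([(10, 10), (11, 11)])
        f2 = self._foci([(10.5, 10.5)])
        frac, _ = rm.overlap_fraction(f1, f2, radius=3.0)
        assert frac == 1.0  # one match, min(n1, n2) = 1

    def test_independent_placements_consistent_with_null(self):
        """Foci placed independently in the same nuclei: the observed match
        count sits inside the central 95% of its own permutation null."""
        cfg = rm.SimPlaConfig(seed=11, n_nuclei=12, image_shape=(256, 256),
                              lambda_by_condition={"r1": 5.0, "r2": 5.0},
                              min_focus_separation=0.0, shared_nuclei=True)
        images, truth = rm.simulate_pla_images(cfg)
        seg = rm.segment_nuclei(images["r1"][0])
        f1 = rm.assign_foci(rm.detect_foci(images["r1"][1]), seg)
        f2 = rm.assign_foci(rm.detect_foci(images["r2"][1]), seg)
        frac, p = rm.overlap_fraction(f1, f2, radius=2.0, seg=seg,
                                      n_permutations=200, seed=1)
        # under the null the permutation p-value should not be extreme
        assert 0.025 <= p or frac == 0.0
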