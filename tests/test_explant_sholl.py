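import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regenquant import explant_sholl as es
from regenquant import simgen
from regenquant.errors import ConfigurationError, InputError, SegmentationError

# ---------------------------------------------------------------------------
# brute-force Sholl oracle: explicit per-pixel distances (min over mask
# boundary pixels) and hand-rolled BFS component counting


def sholl_oracle(skeleton, mask, pixel_size_um, step_um, n_bands,
                 annulus_halfwidth_px=0.5 * np.sqrt(2.0)):
    h, w = mask.shape
    border = []
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w) or not mask[yy, xx]:
                        border.append((y, x))
                        break
    border = np.array(border, dtype=float)
    skel_pts = np.argwhere(skeleton)
    dist = {}
    for y, x in skel_pts:
        if mask[y, x]:
            dist[(y, x)] = 0.0
        else:
            d2 = (border[:, 0] - y) ** 2 + (border[:, 1] - x) ** 2
            dist[(y, x)] = float(np.sqrt(d2.min())) * pixel_size_um

    half = annulus_halfwidth_px * pixel_size_um
    counts = []
    for k in range(1, n_bands + 1):
        r = k * step_um
        members = {p for p, d in dist.items() if abs(d - r) <= half}
        # BFS flood fill over 8-neighbours
        n_comp = 0
        seen = set()
        for p in members:
            if p in seen:
                continue
            n_comp += 1
            stack = [p]
            seen.add(p)
            while stack:
                cy, cx = stack.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        q = (cy + dy, cx + dx)
                        if q in members and q not in seen:
                            seen.add(q)
                            stack.append(q)
        counts.append(n_comp)
    return np.array(counts)


def straight_ray_fixture(n_axons=7, length_um=400.0, pixel_size_um=2.0,
                         radius_um=250.0, angle_offset=0.1):
    size = int(2 * (radius_um + length_um + 70.0) / pixel_size_um)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (xx - c) ** 2 + (yy - c) ** 2 <= (radius_um / pixel_size_um) ** 2
    skeleton = np.zeros((size, size), dtype=bool)
    for k in range(n_axons):
        theta = 2 * np.pi * k / n_axons + angle_offset
        s = np.append(np.arange(0.0, length_um, pixel_size_um / 4), length_um)
        r = (radius_um + s) / pixel_size_um
        skeleton[
            np.round(c + r * np.sin(theta)).astype(int),
            np.round(c + r * np.cos(theta)).astype(int),
        ] = True
    return skeleton, mask


# ---------------------------------------------------------------------------


class TestSegmentExplant:
    def test_iou_with_generator_disk(self, explant_config):
        image, truth = simgen.simulate_explant(explant_config)
        ei = es.ExplantImage(image, explant_config.pixel_size_um)
        mask = es.segment_explant(ei)
        c = truth.data["center_px"]
        r = truth.data["radius_px"]
        yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        disk = (xx - c[1]) ** 2 + (yy - c[0]) ** 2 <= r**2
        iou = (mask & disk).sum() / (mask | disk).sum()
        assert iou >= 0.9

    def test_blank_image_errors(self):
        with pytest.raises(SegmentationError):
            es.segment_explant(es.ExplantImage(np.zeros((64, 64)), 2.0))

    def test_manual_mask_identity(self, rng):
        image = es.ExplantImage(rng.random((32, 32)), 2.0)
        manual = np.zeros((32, 32), dtype=bool)
        manual[10:20, 10:20] = True
        out = es.segment_explant(image, manual_mask=manual)
        np.testing.assert_array_equal(out, manual)


class TestNeuriteSkeleton:
    def test_no_signal_outside(self):
        image = np.zeros((128, 128))
        image[48:80, 48:80] = 10.0
        ei = es.ExplantImage(image, 2.0)
        mask = image > 5
        skel = es.neurite_skeleton(ei, mask)
        assert not skel.any()

    def test_single_axon_follows_polyline(self):
        cfg = simgen.ExplantSimConfig(
            n_axons=1,
            tortuosity=0.0,
            noise_sd=0.0,
            axon_length_um_distribution=simgen.LengthDistribution(
                "constant", {"value": 300.0}, 400.0
            ),
            seed=5,
        )
        image, truth = simgen.simulate_explant(cfg)
        ei = es.ExplantImage(image, cfg.pixel_size_um)
        mask = es.segment_explant(ei)
        skel = es.neurite_skeleton(ei, mask)
        path = truth.data["axon_paths_px"][0]
        skel_pts = np.argwhere(skel)
        assert len(skel_pts) > 0
        # every skeleton pixel within 2 px of the generating polyline
        for y, x in skel_pts:
            d = np.hypot(path[:, 0] - y, path[:, 1] - x).min()
            assert d <= 2.0

    def test_salt_noise_removed(self, rng):
        image = np.zeros((128, 128))
        image[48:80, 48:80] = 10.0
        mask = image > 5
        salt = rng.random((128, 128)) > 0.995
        image[salt] = 8.0
        skel = es.neurite_skeleton(es.ExplantImage(image, 2.0), mask, min_size_um=10.0)
        assert not skel.any()


class TestShollCounts:
    def test_empty_skeleton(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[28:36, 28:36] = True
        res = es.sholl_counts(np.zeros((64, 64), bool), mask, 2.0)
        assert np.all(res.intersect_counts == 0)
        assert res.axon_count == 0
        assert res.no_growth

    def test_straight_rays_exact(self):
        skeleton, mask = straight_ray_fixture()
        res = es.sholl_counts(skeleton, mask, 2.0, 50.0, max_distance_um=500.0)
        np.testing.assert_array_equal(res.intersect_counts[:8], 7)
        np.testing.assert_array_equal(res.intersect_counts[8:], 0)
        assert not res.no_growth

    def test_matches_oracle_small_images(self):
        # small random skeletons, exhaustive comparison with brute force
        for seed in range(5):
            rng = np.random.default_rng(seed)
            mask = np.zeros((96, 96), dtype=bool)
            mask[40:56, 40:56] = True
            skeleton = rng.random((96, 96)) > 0.97
            skeleton &= ~mask
            res = es.sholl_counts(
                skeleton, mask, 2.0, 20.0, max_distance_um=80.0
            )
            expected = sholl_oracle(skeleton, mask, 2.0, 20.0, len(res.distances_um))
            np.testing.assert_array_equal(res.intersect_counts, expected)

    def test_matches_generator_truth(self, explant_config):
        total = matched = 0
        for seed in range(20):
            cfg = dataclasses.replace(explant_config, seed=seed)
            image, truth = simgen.simulate_explant(cfg)
            ei = es.ExplantImage(image, cfg.pixel_size_um)
            mask = es.segment_explant(ei)
            skel = es.neurite_skeleton(ei, mask)
            res = es.sholl_counts(skel, mask, cfg.pixel_size_um)
            radii, crossings = truth.band_crossings(
                50.0, n_bands=len(res.distances_um)
            )
            total += len(radii)
            matched += int(
                np.sum(res.intersect_counts[: len(radii)] == crossings)
            )
        assert matched / total >= 0.95

    def test_intensity_scale_invariance(self, explant_config):
        image, _ = simgen.simulate_explant(explant_config)
        r1 = _pipeline_counts(image, explant_config.pixel_size_um)
        r2 = _pipeline_counts(image * 3.7, explant_config.pixel_size_um)
        np.testing.assert_array_equal(r1.intersect_counts, r2.intersect_counts)

    def test_radial_counts_non_increasing(self):
        skeleton, mask = straight_ray_fixture(n_axons=5, angle_offset=0.4)
        res = es.sholl_counts(skeleton, mask, 2.0, 50.0)
        assert np.all(np.diff(res.intersect_counts) <= 0)

    def test_bad_step_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[12:20, 12:20] = True
        with pytest.raises(ConfigurationError):
            es.sholl_counts(np.zeros((32, 32), bool), mask, 2.0, step_um=0.0)


def _pipeline_counts(image, pixel_size_um):
    ei = es.ExplantImage(image, pixel_size_um)
    mask = es.segment_explant(ei)
    skel = es.neurite_skeleton(ei, mask)
    return es.sholl_counts(skel, mask, pixel_size_um)


class TestSummarizeOutgrowth:
    @pytest.mark.parametrize(
        "total,n_no,expected_no,expected_q",
        [
            (47, 18, 38.3, 61.7),
            (41, 8, 19.5, 80.5),
            (64, 6, 9.4, 90.6),
            (1, 1, 100.0, 0.0),
        ],
    )
    def test_percentages(self, total, n_no, expected_no, expected_q):
        flags = [True] * n_no + [False] * (total - n_no)
        table = es.summarize_outgrowth(flags, ["cond"] * total).to_frame()
        row = table.iloc[0]
        assert row["pct_no_growth"] == expected_no
        assert row["pct_quantified"] == expected_q
        assert row["n_no_growth"] + row["n_quantified"] == row["total_explants"]

    def test_multiple_conditions(self):
        flags = [True, False, False, True, True, False]
        labels = ["a", "a", "a", "b", "b", "b"]
        table = es.summarize_outgrowth(flags, labels).to_frame()
        assert len(table) == 2
        assert table.set_index("condition").loc["a", "n_no_growth"] == 1
        assert table.set_index("condition").loc["b", "n_no_growth"] == 2

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            es.summarize_outgrowth([], [])

    @given(
        st.lists(st.booleans(), min_size=1, max_size=60),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_conservation_property(self, flags):
        table = es.summarize_outgrowth(flags, ["c"] * len(flags)).to_frame()
        row = table.iloc[0]
        assert row["n_no_growth"] + row["n_quantified"] == len(flags)
        assert 0.0 <= row["pct_no_growth"] <= 100.0
        # printed percentages complement within rounding slack
        assert abs(row["pct_no_growth"] + row["pct_quantified"] - 100.0) <= 0.1


class TestScoreCollapse:
    def test_boundary_two_filopodia_not_collapsed(self):
        a = es.GrowthConeAnnotation("e1", "c1", n_filopodia=2, has_lamellipodia=False)
        assert not a.collapsed

    def test_lamellipodia_rescues(self):
        a = es.GrowthConeAnnotation("e1", "c1", n_filopodia=0, has_lamellipodia=True)
        assert not a.collapsed

    def test_enumerated_fraction(self):
        cones = [
            es.GrowthConeAnnotation("e1", f"c{i}", n, lam)
            for i, (n, lam) in enumerate(
                [(0, False), (5, True), (1, False), (3, False)]
            )
        ]
        summary = es.score_collapse(cones)
        assert summary.per_explant["e1"] == pytest.approx(0.5)

    def test_group_stats(self):
        cones = [
            es.GrowthConeAnnotation("e1", "c1", 0, False),  # collapsed
            es.GrowthConeAnnotation("e1", "c2", 4, False),
            es.GrowthConeAnnotation("e2", "c1", 0, False),  # collapsed
            es.GrowthConeAnnotation("e2", "c2", 0, False),  # collapsed
        ]
        summary = es.score_collapse(cones)
        assert summary.per_explant == {"e1": 0.5, "e2": 1.0}
        assert summary.mean == pytest.approx(0.75)
        expected_sem = np.std([0.5, 1.0], ddof=1) / np.sqrt(2)
        assert summary.sem == pytest.approx(expected_sem)

    def test_dict_records_accepted(self):
        summary = es.score_collapse(
            [
                {"explant_id": "e", "cone_id": "c", "n_filopodia": 1,
                 "has_lamellipodia": False}
            ]
        )
        assert summary.per_explant["e"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            es.score_collapse([])
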