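"""Feature extraction: oracle checks on toy masks, scale behaviour,
and out-of-bag importance ranking."""

import numpy as np
import pandas as pd
import pytest

from nucrank import features, synthgen
from nucrank.core_io import ImageRecord, SpotRecord, candidate_from_mask
from nucrank.features import (FeatureConfig, contextual_features,
                              extract_all, feature_importance,
                              fish_features, morphological_features,
                              texture_features)

from conftest import disk_mask, flat_image, make_obj, rough_blob_mask

CFG = FeatureConfig()


def _gift_wrap_hull_area(points: np.ndarray) -> float:
    """Exhaustive convex hull (gift wrapping) + shoelace area oracle."""
    pts = [tuple(p) for p in np.unique(points, axis=0)]
    if len(pts) < 3:
        return 0.0
    start = min(pts)
    hull = [start]
    cur = start
    while True:
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = ((cand[0] - cur[0]) * (p[1] - cur[1]) -
                     (cand[1] - cur[1]) * (p[0] - cur[0]))
            if cross < 0 or (cross == 0 and
                             np.hypot(p[0] - cur[0], p[1] - cur[1]) >
                             np.hypot(cand[0] - cur[0], cand[1] - cur[1])):
                cand = p
        if cand == start:
            break
        hull.append(cand)
        cur = cand
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


class TestMorphological:
    def test_filled_square(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        v, _ = morphological_features(make_obj(m), CFG)
        assert v["area"] == 100
        assert v["solidity"] == pytest.approx(1.0)
        assert v["eccentricity"] == pytest.approx(0.0)
        assert v["num_severe_corners"] == 4

    def test_disk_oracles(self):
        mask = disk_mask(20)
        obj = make_obj(mask)
        v, _ = morphological_features(obj, CFG)
        # brute-force largest-inscribed-circle oracle
        inner = np.argwhere(mask)
        outer = np.argwhere(~mask)
        from scipy.spatial import cKDTree
        r_in = cKDTree(outer).query(inner)[0].max()
        oracle = np.pi * r_in ** 2 / mask.sum()
        assert v["max_circle_ratio"] == pytest.approx(oracle, rel=0.02)
        assert 0.95 <= v["max_circle_ratio"] <= 1.05
        assert v["efd_harmonics"] == 1

    def test_l_shape_solidity_against_hull_oracle(self):
        m = np.zeros((22, 22), bool)
        m[2:18, 2:6] = True    # vertical 16x4 arm
        m[14:18, 2:18] = True  # horizontal 4x16 arm
        obj = make_obj(m)
        v, _ = morphological_features(obj, CFG)
        # hull of pixel corner points matches the pixelised hull closely
        px = np.argwhere(m)
        corners = np.vstack([px + d for d in
                             ((0, 0), (0, 1), (1, 0), (1, 1))])
        oracle = m.sum() / _gift_wrap_hull_area(corners)
        assert v["solidity"] == pytest.approx(oracle, rel=0.05)
        assert v["solidity"] < 0.7  # distinctly non-convex

    def test_solidity_never_exceeds_one(self):
        for seed in range(6):
            v, _ = morphological_features(
                make_obj(rough_blob_mask(15, seed)), CFG)
            assert v["solidity"] <= 1.0 + 1e-9

    def test_scale_behaviour(self):
        small = disk_mask(12)
        big = disk_mask(24)
        vs, _ = morphological_features(make_obj(small), CFG)
        vb, _ = morphological_features(make_obj(big), CFG)
        assert vb["area"] == pytest.approx(4 * vs["area"], rel=0.05)
        assert vb["perimeter"] == pytest.approx(2 * vs["perimeter"],
                                                rel=0.05)
        for inv in ("solidity", "eccentricity", "max_circle_ratio"):
            assert vb[inv] == pytest.approx(vs[inv], abs=0.05)
        assert vb["efd_harmonics"] == vs["efd_harmonics"]

    def test_disk_minimises_perimeter_area_ratio(self):
        disk = disk_mask(20)
        side = int(round(np.sqrt(disk.sum())))
        square = np.zeros((side + 10, side + 10), bool)
        square[5:5 + side, 5:5 + side] = True
        vd, _ = morphological_features(make_obj(disk), CFG)
        vq, _ = morphological_features(make_obj(square), CFG)
        assert vd["perimeter_area_ratio"] < vq["perimeter_area_ratio"]

    def test_box_dimension_straight_polygon(self):
        m = np.zeros((70, 70), bool)
        m[5:65, 5:65] = True
        v, _ = morphological_features(make_obj(m), CFG)
        assert 1.0 <= v["box_dimension"] <= 1.1

    def test_box_dimension_grows_with_roughness(self):
        dims = []
        for rough in (0.02, 0.30):
            vals = [morphological_features(
                make_obj(rough_blob_mask(30, seed, rough)), CFG)[0]
                ["box_dimension"] for seed in range(4)]
            dims.append(np.mean(vals))
        assert dims[1] > dims[0]

    def test_erosion_profile_separates_dumbbell_from_disk(self):
        r = 12
        dumbbell = np.zeros((40, 80), bool)
        from skimage.draw import disk as skdisk
        rr, cc = skdisk((20, 18), r)
        dumbbell[rr, cc] = True
        rr, cc = skdisk((20, 60), r)
        dumbbell[rr, cc] = True
        dumbbell[19:21, 18:60] = True  # 2-px neck
        v_dumb, _ = morphological_features(make_obj(dumbbell), CFG)
        v_disk, _ = morphological_features(
            make_obj(disk_mask(int(np.sqrt(dumbbell.sum() / np.pi)))), CFG)
        assert v_dumb["erosion_profile"] >= 2
        assert v_disk["erosion_profile"] == 1

    def test_determinism(self):
        obj = make_obj(rough_blob_mask(18, 3))
        a, _ = morphological_features(obj, CFG)
        b, _ = morphological_features(obj, CFG)
        assert a == b


class TestTexture:
    def test_constant_region(self):
        m = disk_mask(8)
        img = flat_image(m.shape, 77.0)
        v, _ = texture_features(make_obj(m), img, CFG)
        assert v["intensity_range"] == 0
        assert v["entropy"] == 0
        assert v["glcm_contrast"] == 0

    def test_two_valued_entropy_is_one_bit(self):
        m = np.zeros((10, 10), bool)
        m[1:9, 1:9] = True
        img = np.full((10, 10), 10.0)
        img[1:9, 1:5] = 200.0  # exactly half the 64 in-mask pixels
        v, _ = texture_features(make_obj(m),
                                ImageRecord("img", "s", "c", img), CFG)
        assert v["entropy"] == pytest.approx(1.0)

    def test_checkerboard_glcm_contrast_oracle(self):
        m = np.zeros((8, 8), bool)
        m[:, :] = True
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        obj = make_obj(m)
        v, _ = texture_features(obj, ImageRecord("img", "s", "c", img), CFG)
        # exhaustive pair enumeration over the four distance-1 directions
        q = (img / 255.0 * (CFG.glcm_levels - 1)).astype(int)
        counts = {}
        for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
            for r in range(8):
                for c in range(8):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 8 and 0 <= c2 < 8:
                        for pair in ((q[r, c], q[r2, c2]),
                                     (q[r2, c2], q[r, c])):
                            counts[pair] = counts.get(pair, 0) + 1
        total = sum(counts.values())
        oracle = sum(n * (i - j) ** 2 for (i, j), n in counts.items()) / total
        assert v["glcm_contrast"] == pytest.approx(oracle)


class TestFish:
    def _obj(self):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        return make_obj(m)

    def test_zero_spots_policy(self):
        v, f = fish_features(self._obj(), [], CFG)
        assert v["num_fish"] == 0
        assert v["mean_fish_distance"] == 0 and f["mean_fish_distance"] == 1
        assert f["fish_hull_area_ratio"] == 1

    def test_three_four_five_distance(self):
        obj = self._obj()
        spots = [SpotRecord("a", "img", 10.0, 10.0, "g", obj.object_id),
                 SpotRecord("b", "img", 13.0, 14.0, "g", obj.object_id)]
        v, _ = fish_features(obj, spots, CFG)
        assert v["mean_fish_distance"] == pytest.approx(5.0)

    def test_square_hull_ratio_and_boundary(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True  # 100-pixel mask
        obj = make_obj(m)
        spots = [SpotRecord(s, "img", x, y, "g", obj.object_id)
                 for s, (x, y) in zip("abcd", [(3, 3), (3, 12), (12, 3),
                                               (12, 12)])]
        v, _ = fish_features(obj, spots, CFG)
        assert v["fish_hull_area_ratio"] == pytest.approx(0.81)
        # hull corners sit outside/on the contour -> intersects
        assert v["fish_boundary"] == 1.0
        inner = [SpotRecord(s, "img", x, y, "g", obj.object_id)
                 for s, (x, y) in zip("efg", [(6, 6), (8, 6), (7, 8)])]
        v2, _ = fish_features(obj, inner, CFG)
        assert v2["fish_boundary"] == 0.0


class TestContextual:
    def test_single_candidate(self):
        m = np.zeros((40, 40), bool)
        m[10:20, 10:20] = True
        obj = make_obj(m)
        out = contextual_features([obj], flat_image((40, 40)), CFG)
        v, _ = out[obj.object_id]
        assert v["num_nuclei"] == 1
        assert v["num_neighbors"] == 0
        assert v["betweenness"] == 0

    def test_collinear_path_graph_betweenness(self):
        objs = []
        canvas = np.zeros((30, 100), bool)
        for i, c0 in enumerate((5, 30, 55)):
            m = canvas.copy()
            m[10:20, c0:c0 + 10] = True
            objs.append(candidate_from_mask(m, f"o{i}", "img"))
        out = contextual_features(objs, flat_image((30, 100)), CFG)
        assert out["o1"][0]["betweenness"] == pytest.approx(1.0)
        assert out["o0"][0]["num_neighbors"] == 1
        assert out["o1"][0]["num_neighbors"] == 2

    def test_intensity_ratio_convention(self):
        img = np.full((50, 50), 10.0)
        m = np.zeros((50, 50), bool)
        m[20:30, 20:30] = True
        img[m] = 100.0
        obj = candidate_from_mask(m, "o", "img")
        out = contextual_features([obj], ImageRecord("img", "s", "c", img),
                                  CFG)
        assert out["o"][0]["intensity_band_ratio"] == pytest.approx(0.1)


class TestExtractAll:
    def _dataset(self):
        rng = np.random.default_rng(0)
        img = np.full((120, 120), 30.0) + rng.normal(0, 2, (120, 120))
        mask = np.zeros((120, 120), int)
        mask[10:40, 10:40] = 1
        mask[60:100, 20:55] = 2
        mask[50:80, 80:110] = 3
        img[mask > 0] = 120.0
        image = ImageRecord("img", "S01", "S01C01", img)
        from nucrank.core_io import load_candidates, assign_spots
        cands = load_candidates(mask, image)
        spots = assign_spots(
            [SpotRecord("s1", "img", 20, 20, "g"),
             SpotRecord("s2", "img", 30, 75, "g")], cands, image.shape)
        return {"img": cands}, {"img": image}, spots

    def test_default_column_count(self):
        cands, imgs, spots = self._dataset()
        tab = extract_all(cands, imgs, spots)
        n_feat = (len(features.MORPHOLOGICAL) + len(features.TEXTURE) +
                  len(features.FISH))
        n_flags = sum(len(features.MISSING_CAPABLE[f])
                      for f in ("morphological", "texture", "fish"))
        assert tab.shape == (3, 1 + n_feat + n_flags)
        assert list(tab.columns[1:1 + len(features.MORPHOLOGICAL)]) == \
            features.MORPHOLOGICAL

    def test_rerun_identical(self):
        cands, imgs, spots = self._dataset()
        a = extract_all(cands, imgs, spots)
        b = extract_all(cands, imgs, spots)
        pd.testing.assert_frame_equal(a, b)

    def test_contextual_adds_five_columns(self):
        cands, imgs, spots = self._dataset()
        base = extract_all(cands, imgs, spots)
        full = extract_all(cands, imgs, spots,
                           families=("morphological", "texture", "fish",
                                     "contextual"))
        extra = set(full.columns) - set(base.columns)
        assert set(features.CONTEXTUAL) <= extra
        assert len([c for c in extra if not c.endswith("_missing")]) == 5

    def test_unknown_family_rejected(self):
        cands, imgs, spots = self._dataset()
        with pytest.raises(ValueError, match="family"):
            extract_all(cands, imgs, spots, families=("morphological",
                                                      "spectral"))


class TestImportance:
    def _make_data(self, seed, n=150):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=["solidity", "f1", "f2", "f3", "f4",
                                  "noise"])
        y = (X["solidity"] > 0).astype(float)
        return X, y

    def test_driving_feature_ranked_first(self):
        wins = 0
        for seed in range(100):
            X, y = self._make_data(seed)
            rep = feature_importance(X, y, seed=seed, n_trees=40)
            if rep.table.iloc[0]["feature"] == "solidity":
                wins += 1
        assert wins >= 95

    def test_noise_below_informative(self):
        rng = np.random.default_rng(0)
        below = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(150, 3)),
                             columns=["a", "b", "noise"])
            y = (X["a"] + 0.5 * X["b"] > 0).astype(float)
            rep = feature_importance(X, y, seed=seed, n_trees=40)
            t = rep.table.set_index("feature")
            if t.loc["noise", "importance"] < min(
                    t.loc["a", "importance"], t.loc["b", "importance"]):
                below += 1
        assert below >= 95

    def test_duplicated_feature_flagged_collinear(self):
        X, y = self._make_data(0)
        X["solidity_copy"] = X["solidity"]
        rep = feature_importance(X, y, seed=0, n_trees=60)
        assert ("solidity", "solidity_copy") in rep.collinear_pairs
        t = rep.table.set_index("feature")
        assert t.loc["solidity", "importance"] > 0
        assert t.loc["solidity_copy", "importance"] > 0

    def test_constant_labels_rejected(self):
        X, _ = self._make_data(0)
        with pytest.raises(ValueError, match="constant"):
            feature_importance(X, np.ones(len(X)), seed=0)
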