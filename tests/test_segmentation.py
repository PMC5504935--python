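import numpy as np
import pytest

from p300ifce.color_pattern import angle_map
from p300ifce.fuzzy_engine import FuzzyParams, match_decision
from p300ifce.segmentation import (
    CONNECTIVITIES,
    GrowthConfig,
    NoObjectError,
    Subregion,
    UnmatchedStartError,
    extract_object,
    extract_subregions,
    fill_gaps,
    find_start_pixel,
    grow_subregion,
    rasterize,
    select_object,
)

RED = (200, 30, 30)
BLACK = (0, 0, 0)
PARAMS = FuzzyParams(alpha1=0.2, alpha2=0.3, rho_m=0.2, sigma=0.5, r=float("inf"))


def image_of(grid):
    return np.array([[list(px) for px in row] for row in grid], dtype=np.uint8)


def brute_force_closure(image, start, seed, params, connectivity):
    """Oracle: iterate 'add any matched neighbor of the set' to a fixed point."""
    M, N = image.shape[:2]
    matched = {
        (m, n)
        for m in range(M)
        for n in range(N)
        if tuple(image[m, n]) != (0, 0, 0) and match_decision(image[m, n], seed, params)
    }
    region = {start}
    changed = True
    while changed:
        changed = False
        for (m, n) in list(region):
            for dm, dn in CONNECTIVITIES[connectivity]:
                nb = (m + dm, n + dn)
                if nb in matched and nb not in region:
                    region.add(nb)
                    changed = True
    return region


class TestFindStartPixel:
    def test_exact_seed_pixel_wins(self):
        img = image_of([[BLACK, RED], [(90, 90, 90), (10, 200, 10)]])
        remaining = {(m, n) for m in range(2) for n in range(2)}
        assert find_start_pixel(img, RED, remaining) == (0, 1)

    def test_minimal_angle_brute_force(self, rng):
        img = rng.integers(1, 256, size=(2, 2, 3)).astype(np.uint8)
        remaining = {(m, n) for m in range(2) for n in range(2)}
        amap = angle_map(img, RED)
        expected = min(remaining, key=lambda c: (amap[c], c))
        assert find_start_pixel(img, RED, remaining) == expected

    def test_tie_break_row_major(self):
        img = image_of([[BLACK, RED], [RED, BLACK]])  # two identical minima
        remaining = {(0, 1), (1, 0)}
        assert find_start_pixel(img, RED, remaining) == (0, 1)

    def test_empty_remaining(self):
        img = image_of([[RED]])
        with pytest.raises(ValueError):
            find_start_pixel(img, RED, set())


class TestGrowSubregion:
    def make_block_image(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        img[1:3, 1:3] = RED
        return img

    def test_uniform_block(self):
        img = self.make_block_image()
        sub = grow_subregion(img, (1, 1), RED, PARAMS, GrowthConfig(r=float("inf")))
        assert sub.size == 4
        assert sub.coordinates == frozenset({(1, 1), (1, 2), (2, 1), (2, 2)})

    def test_diagonal_blocks_4_adjacent_vs_8(self):
        img = np.zeros((6, 6, 3), dtype=np.uint8)
        img[0:2, 0:2] = RED
        img[2:4, 2:4] = RED  # touches the first block at corner (1,1)-(2,2)
        four = grow_subregion(
            img, (0, 0), RED, PARAMS, GrowthConfig(connectivity="4-adjacent", r=float("inf"))
        )
        eight = grow_subregion(
            img, (0, 0), RED, PARAMS, GrowthConfig(connectivity="8-neighbor", r=float("inf"))
        )
        assert four.size == 4  # only the block containing the start
        assert eight.size == 8  # corner contact merges both

    def test_unmatched_start(self):
        img = self.make_block_image()
        with pytest.raises(UnmatchedStartError):
            grow_subregion(img, (0, 0), RED, PARAMS, GrowthConfig(r=float("inf")))

    @pytest.mark.parametrize("connectivity", sorted(CONNECTIVITIES))
    def test_equals_brute_force_fixed_point_16x16(self, connectivity, rng):
        """Growth equals the naive fixed-point closure on random fixtures."""
        cfg = GrowthConfig(connectivity=connectivity, r=float("inf"))
        for _ in range(5):
            # coarse palette so matched regions have nontrivial shapes
            palette = np.array([RED, (180, 40, 170), (30, 200, 40), (210, 60, 40)])
            img = palette[rng.integers(0, 4, size=(16, 16))].astype(np.uint8)
            matched_any = [
                (m, n)
                for m in range(16)
                for n in range(16)
                if match_decision(img[m, n], RED, PARAMS)
            ]
            start = matched_any[0]
            sub = grow_subregion(img, start, RED, PARAMS, cfg)
            assert set(sub.coordinates) == brute_force_closure(
                img, start, RED, PARAMS, connectivity
            )


class TestExtractSubregions:
    def test_no_match_gives_empty_list(self):
        img = np.full((4, 4, 3), (30, 200, 40), dtype=np.uint8)
        assert extract_subregions(img, RED, PARAMS) == []

    def test_two_disjoint_blocks(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[0:3, 0:3] = RED  # 9 px
        img[5:7, 5:7] = RED  # 4 px
        subs = extract_subregions(img, RED, PARAMS, GrowthConfig(r=float("inf")))
        assert sorted(s.size for s in subs) == [4, 9]

    def test_uniform_image_single_subregion(self):
        img = np.full((6, 7, 3), RED, dtype=np.uint8)
        subs = extract_subregions(img, RED, PARAMS, GrowthConfig(r=float("inf")))
        assert len(subs) == 1 and subs[0].size == 42

    def test_distance_gate_stops_far_colors(self):
        img = np.zeros((4, 8, 3), dtype=np.uint8)
        img[0:2, 0:2] = RED
        img[0:2, 5:7] = (140, 20, 20)  # same hue family, far in RGB
        gated = extract_subregions(img, RED, PARAMS, GrowthConfig(r=1000.0))
        open_ = extract_subregions(img, RED, PARAMS, GrowthConfig(r=float("inf")))
        assert len(gated) == 1 and len(open_) == 2

    def test_subregions_disjoint(self, rng):
        palette = np.array([RED, (190, 35, 35), (30, 200, 40)])
        img = palette[rng.integers(0, 3, size=(12, 12))].astype(np.uint8)
        subs = extract_subregions(img, RED, PARAMS, GrowthConfig(r=float("inf")))
        seen = set()
        for s in subs:
            assert not (s.coordinates & seen)
            seen |= s.coordinates


class TestSelectObject:
    def test_largest_wins(self):
        a = Subregion(frozenset((0, n) for n in range(9)))
        b = Subregion(frozenset((1, n) for n in range(4)))
        assert select_object([b, a]) is a

    def test_single_is_identity(self):
        a = Subregion(frozenset({(0, 0)}))
        assert select_object([a]) is a

    def test_tie_break_first_extracted(self):
        a = Subregion(frozenset((0, n) for n in range(7)))
        b = Subregion(frozenset((1, n) for n in range(7)))
        assert select_object([a, b]) is a

    def test_empty_raises(self):
        with pytest.raises(NoObjectError):
            select_object([])


class TestFillGaps:
    @pytest.mark.parametrize(
        "row, threshold, expected",
        [
            ([1, 0, 1], 2, [1, 1, 1]),
            ([1, 0, 0, 1], 2, [1, 0, 0, 1]),  # run length 2 is not < 2
            ([0, 0, 1], 5, [0, 0, 1]),  # not bounded on both sides
            ([1, 0, 0, 1], 3, [1, 1, 1, 1]),
        ],
    )
    def test_rows(self, row, threshold, expected):
        out = fill_gaps(np.array([row], dtype=np.uint8), threshold)
        assert out.tolist() == [expected]

    def test_rows_then_columns(self):
        mask = np.array([[1, 1, 1], [1, 0, 0], [1, 1, 1]], dtype=np.uint8)
        # row pass cannot fill (0,0)-run unbounded right; column pass fills col 1 and 2
        assert fill_gaps(mask, 2).tolist() == [[1, 1, 1], [1, 1, 1], [1, 1, 1]]

    def test_monotone_and_idempotent(self, rng):
        mask = (rng.random((12, 12)) < 0.5).astype(np.uint8)
        once = fill_gaps(mask, 3)
        assert np.all(once >= mask)  # never clears a set pixel
        assert np.array_equal(fill_gaps(once, 3), once)


class TestExtractObject:
    def test_dominant_blob_with_speckles(self, dataset):
        from p300ifce.synthetic_data import make_scene, mask_iou, single_object_scene_spec

        spec = single_object_scene_spec("O1", rng_seed=7)
        image, truth = make_scene(spec)
        mask = extract_object(image, dataset["O1"])
        assert mask_iou(mask, truth["O1"]) >= 0.95

    def test_scale_invariance_gate_disabled(self, dataset):
        from p300ifce.synthetic_data import SceneSpec, make_scene, single_object_scene_spec

        cfg = GrowthConfig(r=float("inf"))
        base = single_object_scene_spec("O2", illumination=1.0, rng_seed=11)
        half = single_object_scene_spec("O2", illumination=0.5, rng_seed=11)
        m1 = extract_object(make_scene(base)[0], dataset["O2"], cfg)
        m2 = extract_object(make_scene(half)[0], dataset["O2"], cfg)
        assert np.array_equal(m1, m2)

    def test_no_object_error(self, dataset):
        img = np.full((8, 8, 3), (30, 200, 40), dtype=np.uint8)
        with pytest.raises(NoObjectError):
            extract_object(img, dataset["O1"])

    def test_mask_is_binary(self, dataset):
        from p300ifce.synthetic_data import make_scene, single_object_scene_spec

        image, _ = make_scene(single_object_scene_spec("O3", rng_seed=3))
        mask = extract_object(image, dataset["O3"])
        assert set(np.unique(mask)) <= {0, 1}
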