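"""Airway segmentation, tree extraction, and cross-sectional morphometry."""

import numpy as np
import pytest

import qctlung as q
from conftest import make_cylinder
from qctlung.airways import (
    AirwaySegment,
    AirwayTree,
    GenerationSummary,
    extract_centerline_tree,
    measure_segment,
    normalize_to_subject,
    per_generation_summary,
    tree_from_json,
    tree_to_json,
)
from qctlung.core import CTVolume, RegionMask

SEED = (19, 60, 60)  # inside the default phantom's trachea


def dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="module")
def hf_lumen(hf_phantom):
    _, vol, _ = hf_phantom
    return q.segment_airway_tree(vol, SEED)


@pytest.fixture(scope="module")
def hf_tree(hf_phantom, hf_lumen):
    _, vol, _ = hf_phantom
    with pytest.warns(UserWarning, match="cyclic"):
        tree = extract_centerline_tree(hf_lumen, spacing=vol.spacing,
                                       root_hint=SEED)
    return tree


class TestSegmentAirwayTree:
    def test_phantom_lumen_recovery(self, hf_phantom, hf_lumen):
        _, _, truth = hf_phantom
        assert dice(hf_lumen.mask, truth.airway_lumen_mask.mask) >= 0.90

    def test_seed_in_soft_tissue_raises(self, hf_phantom):
        _, vol, _ = hf_phantom
        with pytest.raises(ValueError, match="not below"):
            q.segment_airway_tree(vol, (64, 60, 60))  # body soft tissue

    def test_seed_in_ambient_air_unsegmentable(self, hf_phantom):
        _, vol, _ = hf_phantom
        with pytest.raises(ValueError, match="unsegmentable|border"):
            q.segment_airway_tree(vol, (0, 0, 0))

    def test_punched_wall_leak_contained(self, hf_phantom):
        """A one-voxel perforation of a generation-3 wall must trigger the
        leak rollback: the accepted mask stays near the truth volume."""
        _, vol, truth = hf_phantom
        vals = vol.values.copy()
        seg = next(s for s in truth.tree.segments if s.generation == 3)
        mid = 0.5 * (seg.centerline[0] + seg.centerline[-1])
        # carve a thin channel through the wall along the slice axis
        wall = truth.airway_wall_mask.mask
        zi, yi, xi = np.round(mid).astype(int)
        carved = 0
        for dz in range(-15, 16):
            for dy in (-1, 0, 1):
                z = zi + dz
                if 0 <= z < vals.shape[0] and wall[z, yi + dy, xi]:
                    vals[z, yi + dy, xi] = -1000.0
                    carved += 1
        assert carved > 0
        leaky = CTVolume(vals, spacing=vol.spacing)
        lumen = q.segment_airway_tree(leaky, SEED)
        assert lumen.mask.sum() <= 1.1 * truth.airway_lumen_mask.mask.sum()


class TestExtractCenterlineTree:
    def test_symmetric_phantom_topology(self, hf_tree):
        assert len(hf_tree.segments) == 2**6 - 1
        assert hf_tree.max_generation == 6

    def test_generation_labels_are_bfs_depths(self, hf_tree):
        by_id = {s.id: s for s in hf_tree.segments}
        for s in hf_tree.segments:
            if s.parent_id is None:
                assert s.generation == 1
            else:
                assert s.generation == by_id[s.parent_id].generation + 1

    def test_straight_tube_single_segment(self):
        vals = np.full((60, 30, 30), 30.0)
        zz, yy, xx = np.meshgrid(np.arange(60), np.arange(30), np.arange(30),
                                 indexing="ij")
        r = np.hypot(yy - 15, xx - 15)
        vals[(r < 5) & (zz > 2) & (zz < 57)] = -1000.0
        lumen = RegionMask((vals < -500), label="airway_lumen")
        tree = extract_centerline_tree(lumen)
        assert len(tree.segments) == 1
        assert tree.root.generation == 1

    def test_trifurcation_children_all_next_generation(self):
        # three tubes diverging from the end of a parent tube
        from qctlung.phantom import _raster_tree

        # parent length >> 3x radius: thinning recedes from blunt tube ends
        # by about three radii, so a short parent would vanish entirely
        parent = {"id": 0, "parent": None, "generation": 1,
                  "p0": np.array([5.0, 30.0, 30.0]),
                  "p1": np.array([50.0, 30.0, 30.0]),
                  "radius": 4.0, "wall": 1.5}
        segs = [parent]
        for i, d in enumerate([(1, 0.7, 0), (1, -0.35, 0.6), (1, -0.35, -0.6)]):
            d = np.asarray(d, float)
            d /= np.linalg.norm(d)
            segs.append({"id": i + 1, "parent": 0, "generation": 2,
                         "p0": parent["p1"], "p1": parent["p1"] + 22 * d,
                         "radius": 2.8, "wall": 1.2})
        lumen, _, _ = _raster_tree(segs, (85, 60, 60), np.ones(3))
        tree = extract_centerline_tree(RegionMask(lumen, label="airway_lumen"),
                                       root_hint=(5, 30, 30))
        gens = sorted(s.generation for s in tree.segments)
        assert gens == [1, 2, 2, 2]

    def test_disconnected_mask_raises(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:6, 5:9, 5:9] = True
        mask[12:16, 5:9, 5:9] = True
        with pytest.raises(ValueError, match="connected components"):
            extract_centerline_tree(RegionMask(mask))


class TestMeasureSegment:
    @pytest.mark.parametrize("radius,wall", [(2.0, 1.0), (4.0, 1.5), (6.0, 2.5)])
    @pytest.mark.parametrize("oblique", [False, True])
    def test_cylinder_recovery_at_half_mm(self, radius, wall, oblique):
        spacing = 0.5
        vol, cl = make_cylinder(radius, wall, spacing, oblique=oblique)
        area, w, n, flag = measure_segment(vol, cl)
        true_area = np.pi * radius**2
        annulus = np.pi * ((radius + spacing) ** 2 - radius**2)
        assert flag == "ok" and n >= 3
        assert abs(area - true_area) <= max(0.05 * true_area, annulus)
        assert abs(w - wall) <= 0.5 * spacing

    def test_sub_voxel_wall_flagged_unreliable(self):
        vol, cl = make_cylinder(4.0, 0.4, spacing=1.0)
        _, _, _, flag = measure_segment(vol, cl)
        assert flag in ("unreliable", "wall_unreliable")

    def test_no_outer_contrast_flags_wall_only(self):
        # wall merging into surrounding soft tissue: area holds, wall doesn't
        vol, cl = make_cylinder(6.0, 2.0, spacing=0.5, background_hu=30.0)
        area, w, _, flag = measure_segment(vol, cl)
        assert flag == "wall_unreliable"
        assert area == pytest.approx(np.pi * 36.0, rel=0.06)
        assert np.isnan(w)

    def test_too_short_centerline_raises(self):
        vol, cl = make_cylinder(4.0, 1.5, spacing=1.0)
        with pytest.raises(ValueError, match="at least 3"):
            measure_segment(vol, cl[:2])


class TestSummaries:
    def test_area_halves_per_generation_on_phantom(self, hf_phantom, hf_tree):
        _, vol, _ = hf_phantom
        q.measure_tree(vol, hf_tree)
        gens = per_generation_summary(hf_tree)
        areas = {g.generation: g.mean_area for g in gens if g.flag == "ok"}
        ratios = [areas[g + 1] / areas[g] for g in sorted(areas)[:-1]
                  if g + 1 in areas]
        assert ratios and all(0.4 < r < 0.6 for r in ratios)

    def test_max_generation_single_row(self, hf_tree):
        rows = per_generation_summary(hf_tree, max_generation=1)
        assert len(rows) == 1 and rows[0].generation == 1

    def test_generations_beyond_max_dropped(self):
        segs = [AirwaySegment(id=0, parent_id=None, generation=1,
                              centerline=np.zeros((3, 3)),
                              mean_lumen_area=100.0, mean_wall_thickness=2.0,
                              quality_flag="ok")]
        sid = 0
        for gen in range(2, 8):
            sid += 1
            segs.append(AirwaySegment(id=sid, parent_id=sid - 1, generation=gen,
                                      centerline=np.zeros((3, 3)),
                                      mean_lumen_area=100.0 / 2**gen,
                                      mean_wall_thickness=1.0,
                                      quality_flag="ok"))
        rows = per_generation_summary(AirwayTree(segments=segs), max_generation=6)
        assert max(r.generation for r in rows) == 6

    def test_missing_generation_flagged_absent(self):
        tree = AirwayTree(segments=[AirwaySegment(
            id=0, parent_id=None, generation=1, centerline=np.zeros((3, 3)),
            mean_lumen_area=100.0, mean_wall_thickness=2.0, quality_flag="ok")])
        rows = per_generation_summary(tree, max_generation=3)
        assert [r.flag for r in rows] == ["ok", "absent", "absent"]

    def test_normalization_arithmetic(self):
        s = GenerationSummary(generation=1, mean_area=245.0, mean_wall=2.5,
                              n_segments=1)
        out = normalize_to_subject(s, tlc=7.0)
        assert out.area_over_tlc == pytest.approx(35.0)
        s2 = GenerationSummary(generation=2, mean_area=250.0, mean_wall=2.5,
                               n_segments=1)
        assert normalize_to_subject(s2, 7.0).wall_over_area == pytest.approx(0.01)

    def test_normalization_scaling_law(self):
        # doubling the linear scale (wall x2, area x4) halves wall/area and
        # quadruples area/TLC at fixed TLC
        s = GenerationSummary(generation=2, mean_area=100.0, mean_wall=2.0,
                              n_segments=1)
        doubled = GenerationSummary(generation=2, mean_area=400.0, mean_wall=4.0,
                                    n_segments=1)
        a = normalize_to_subject(s, 6.0)
        b = normalize_to_subject(doubled, 6.0)
        assert b.wall_over_area == pytest.approx(0.5 * a.wall_over_area)
        assert b.area_over_tlc == pytest.approx(4.0 * a.area_over_tlc)

    def test_invalid_tlc_raises(self):
        s = GenerationSummary(generation=1, mean_area=245.0, mean_wall=2.5,
                              n_segments=1)
        with pytest.raises(ValueError, match="TLC"):
            normalize_to_subject(s, 0.0)


class TestTreeInvariantsAndSerialization:
    def test_tree_rejects_bad_generation_labels(self):
        with pytest.raises(ValueError, match="generation"):
            AirwayTree(segments=[
                AirwaySegment(id=0, parent_id=None, generation=1,
                              centerline=np.zeros((3, 3))),
                AirwaySegment(id=1, parent_id=0, generation=3,
                              centerline=np.zeros((3, 3))),
            ])

    def test_tree_requires_single_root(self):
        with pytest.raises(ValueError, match="root"):
            AirwayTree(segments=[
                AirwaySegment(id=0, parent_id=None, generation=1,
                              centerline=np.zeros((3, 3))),
                AirwaySegment(id=1, parent_id=None, generation=1,
                              centerline=np.zeros((3, 3))),
            ])

    def test_json_round_trip(self, hf_tree):
        text = tree_to_json(hf_tree)
        back = tree_from_json(text)
        assert len(back.segments) == len(hf_tree.segments)
        for a, b in zip(hf_tree.segments, back.segments):
            assert a.generation == b.generation
            assert np.allclose(a.centerline, b.centerline)
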