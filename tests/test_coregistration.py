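"""Slab-model contour transfer, tumour volumes/areas and rigid refinement."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from histopet.coregistration import (
    SectionGeometry,
    build_tumour_areas,
    build_tumour_volume,
    chain_lesions,
    refine_rigid,
    transfer_contour,
    transform_mask,
)
from histopet.histology import HistoArea
from histopet.synthetic import PhantomSpec, generate_phantom, simulate_pet
from histopet.transforms import Affine, TransformChain
from histopet.volumes import EmptyRegionError, ScalarVolume

from conftest import make_volume

GEOM = SectionGeometry(base_z=-20.0)


def square_area(side_mm=10.0, center=(0.0, 0.0), section=3, hscore=100.0, aid="A1"):
    h = side_mm / 2 * 1000.0
    cx, cy = center[0] * 1000.0, center[1] * 1000.0
    poly = Polygon(
        [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
    )
    return HistoArea(
        patient_id="P1", section=section, area_id=aid, polygon=poly, hscore=hscore
    )


def circle_area(radius_mm, center=(0.0, 0.0), section=3, hscore=100.0, aid="A1"):
    poly = Point(center[0] * 1000, center[1] * 1000).buffer(radius_mm * 1000, quad_segs=32)
    return HistoArea(
        patient_id="P1", section=section, area_id=aid, polygon=poly, hscore=hscore
    )


class TestTransferContour:
    def test_identity_chain_gives_slab_prism(self, small_grid):
        area = square_area(side_mm=10.0)
        mask = transfer_contour(area, GEOM, TransformChain.identity(), small_grid, 4)
        # 10 x 10 mm square through a 4 mm slab
        assert mask.volume_ml() == pytest.approx(0.4, rel=0.02)
        z0, z1 = GEOM.slab_bounds(3)
        pts, _ = mask.fine_centers()
        assert pts[:, 2].min() >= z0 - 0.5 and pts[:, 2].max() <= z1 + 0.5

    def test_translation_equivariance(self, small_grid):
        """A 10 mm translation chain shifts the occupancy by exactly 5 voxels."""
        area = square_area(side_mm=12.0)
        ident = transfer_contour(area, GEOM, TransformChain.identity(), small_grid, 4)
        moved = transfer_contour(
            area,
            GEOM,
            TransformChain([Affine.translation((10.0, 0.0, 0.0))]),
            small_grid,
            4,
        )
        w_i, off_i = ident.voxel_weights()
        w_m, off_m = moved.voxel_weights()
        assert np.asarray(off_m)[0] - np.asarray(off_i)[0] == 5
        np.testing.assert_allclose(w_m, w_i, atol=1e-12)

    def test_volume_preserved_under_rigid_chain(self, small_grid):
        area = circle_area(7.0)
        ident = transfer_contour(area, GEOM, TransformChain.identity(), small_grid, 4)
        rigid = Affine.translation((3.3, -2.1, 1.7)) @ Affine.rotation(
            (0, 0, 1), 4.0, (0, 0, 0)
        )
        moved = transfer_contour(area, GEOM, TransformChain([rigid]), small_grid, 4)
        assert moved.volume_ml() == pytest.approx(ident.volume_ml(), rel=0.01)

    def test_phantom_truth_round_trip_dice(self):
        """Transfer through a misregistered chain, undo with the recorded truth."""
        spec = PhantomSpec(
            n_lesions=1, lesion_radius_range=(7.0, 9.0), noise_sd=0.0,
            psf_fwhm=0.0, misregistration_range=(4.0, 10.0),
        )
        ph = generate_phantom(spec, 5)
        area = max(ph.areas, key=lambda a: a.area_um2)
        displaced = transfer_contour(area, ph.geom, ph.chain, ph.pet.grid, 4)
        restored = transform_mask(displaced, ph.truth.misregistration.inverse())
        aligned = transfer_contour(
            area, ph.geom, TransformChain.identity(), ph.pet.grid, 4
        )
        fa = np.zeros(ph.pet.grid.shape)
        fb = np.zeros(ph.pet.grid.shape)
        wa, _ = aligned.voxel_weights()
        wb, _ = restored.voxel_weights()
        fa[aligned.bbox_slices()] = wa
        fb[restored.bbox_slices()] = wb
        dice = 2 * np.minimum(fa, fb).sum() / (fa.sum() + fb.sum())
        assert dice >= 0.98

    def test_section_not_covered_raises(self, small_grid):
        chain = TransformChain([], section_transforms={1: Affine.identity()})
        with pytest.raises(KeyError):
            transfer_contour(square_area(section=3), GEOM, chain, small_grid, 4)

    def test_area_outside_grid_raises_empty(self, small_grid):
        area = square_area(center=(500.0, 0.0))
        with pytest.raises(EmptyRegionError):
            transfer_contour(area, GEOM, TransformChain.identity(), small_grid, 4)


class TestBuildTumourVolume:
    def test_gap_interpolates_to_cylinder(self, small_grid):
        """Identical circles on sections 2 and 4 fill section 3 with the circle."""
        a2 = circle_area(8.0, section=2, aid="A2")
        a4 = circle_area(8.0, section=4, aid="A4")
        tv = build_tumour_volume([a2, a4], GEOM, TransformChain.identity(), small_grid, 4)
        z0 = GEOM.slab_bounds(2)[0]
        z1 = GEOM.slab_bounds(4)[1]

        def cylinder(pts):
            in_z = (pts[:, 2] >= z0) & (pts[:, 2] < z1)
            return in_z & (np.linalg.norm(pts[:, :2], axis=1) <= 8.0)

        from histopet.volumes import rasterize_predicate

        oracle = rasterize_predicate(
            cylinder, small_grid, 4, (-8, -8, z0), (8, 8, z1)
        )
        fa = np.zeros(small_grid.shape)
        fb = np.zeros(small_grid.shape)
        wa, _ = tv.mask.voxel_weights()
        wb, _ = oracle.voxel_weights()
        fa[tv.mask.bbox_slices()] = wa
        fb[oracle.bbox_slices()] = wb
        dice = 2 * np.minimum(fa, fb).sum() / (fa.sum() + fb.sum())
        assert dice >= 0.95

    def test_single_section_is_extrusion_only(self, small_grid):
        a = circle_area(6.0, section=3)
        tv = build_tumour_volume([a], GEOM, TransformChain.identity(), small_grid, 4)
        z0, z1 = GEOM.slab_bounds(3)
        pts, _ = tv.mask.fine_centers()
        assert pts[:, 2].min() >= z0 - 0.5 and pts[:, 2].max() < z1 + 0.5
        assert tv.mask.volume_ml() == pytest.approx(np.pi * 36 * 4 / 1000, rel=0.02)

    def test_weighted_hscore_of_constituents(self, small_grid):
        a = circle_area(6.0, section=2, hscore=80.0, aid="A")
        b = circle_area(6.0, section=3, hscore=120.0, aid="B")
        tv = build_tumour_volume([a, b], GEOM, TransformChain.identity(), small_grid, 4)
        assert tv.hscore.mean == pytest.approx(100.0)  # equal polygon areas
        assert tv.constituent_ids == ("A", "B")

    def test_mixed_patients_raise(self, small_grid):
        a = circle_area(5.0, section=2, aid="A")
        b = circle_area(5.0, section=3, aid="B")
        b.patient_id = "P2"
        with pytest.raises(ValueError, match="patients"):
            build_tumour_volume([a, b], GEOM, TransformChain.identity(), small_grid, 4)


class TestChainLesions:
    def test_disjoint_lesions_not_bridged(self):
        a = circle_area(4.0, center=(-10, 0), section=2, aid="A")
        b = circle_area(4.0, center=(-10, 0), section=3, aid="B")
        c = circle_area(4.0, center=(10, 0), section=2, aid="C")
        groups = chain_lesions([a, b, c])
        assert sorted(sorted(x.area_id for x in g) for g in groups) == [["A", "B"], ["C"]]

    def test_same_section_never_chained_directly(self):
        a = circle_area(4.0, center=(0, 0), section=2, aid="A")
        b = circle_area(4.0, center=(1, 0), section=2, aid="B")
        groups = chain_lesions([a, b])
        assert len(groups) == 2

    def test_transitive_chaining(self):
        areas = [
            circle_area(4.0, section=s, aid=f"S{s}") for s in (2, 3, 4, 5)
        ]
        groups = chain_lesions(areas)
        assert len(groups) == 1 and len(groups[0]) == 4


class TestBuildTumourAreas:
    def test_one_area_per_group(self, small_grid):
        hs = {"very_low": 10.0, "low": 100.0, "medium": 150.0, "high": 250.0}
        areas = [
            circle_area(5.0, center=(dx, 0), section=3, hscore=h, aid=lab)
            for (lab, h), dx in zip(hs.items(), (-15, -5, 5, 15))
        ]
        tas = build_tumour_areas(
            areas, geom=GEOM, chain=TransformChain.identity(), grid=small_grid
        )
        assert [ta.group for ta in tas] == ["very_low", "low", "medium", "high"]
        assert all(ta.hscore.sd == 0.0 for ta in tas)

    def test_same_group_combined_with_weighted_stats(self, small_grid):
        a = circle_area(5.0, center=(-8, 0), section=2, hscore=80.0, aid="A")
        b = circle_area(5.0, center=(8, 0), section=2, hscore=120.0, aid="B")
        tas = build_tumour_areas(
            [a, b], geom=GEOM, chain=TransformChain.identity(), grid=small_grid
        )
        assert len(tas) == 1
        ta = tas[0]
        assert ta.group == "low"
        assert ta.hscore.mean == pytest.approx(100.0)
        assert ta.hscore.sd == pytest.approx(20.0)
        assert set(ta.constituent_ids) == {"A", "B"}

    def test_constituents_partition_input(self, small_grid):
        rng = np.random.default_rng(2)
        areas = [
            circle_area(
                4.0, center=(float(rng.uniform(-12, 12)), float(rng.uniform(-10, 10))),
                section=int(rng.integers(2, 8)), hscore=float(rng.uniform(0, 300)),
                aid=f"A{i}",
            )
            for i in range(9)
        ]
        tas = build_tumour_areas(
            areas, geom=GEOM, chain=TransformChain.identity(), grid=small_grid
        )
        all_ids = sorted(i for ta in tas for i in ta.constituent_ids)
        assert all_ids == sorted(a.area_id for a in areas)

    def test_no_z_interpolation(self, small_grid):
        a = circle_area(6.0, section=2, hscore=100.0, aid="A")
        b = circle_area(6.0, section=5, hscore=100.0, aid="B")
        tas = build_tumour_areas(
            [a, b], geom=GEOM, chain=TransformChain.identity(), grid=small_grid
        )
        pts, _ = tas[0].mask.fine_centers()
        zs = pts[:, 2]
        gap_lo = GEOM.slab_bounds(2)[1] + 0.5
        gap_hi = GEOM.slab_bounds(5)[0] - 0.5
        assert not np.any((zs > gap_lo) & (zs < gap_hi))


class TestRefineRigid:
    def _hot_pet(self, grid, center, radius=7.0, value=10.0, fwhm=4.8):
        vals = np.zeros(grid.shape)
        idx = np.indices(grid.shape).reshape(3, -1).T
        pts = grid.index_to_world(idx)
        vals.ravel()[np.linalg.norm(pts - center, axis=1) <= radius] = value
        return simulate_pet(make_volume(grid, vals), fwhm, 0.0, seed=0)

    def test_centred_region_returns_identity(self, small_grid):
        from histopet.pet_metrics import ellipsoid_region

        pet = self._hot_pet(small_grid, np.zeros(3))
        region = ellipsoid_region((0, 0, 0), (7, 7, 7), small_grid, 4)
        res = refine_rigid(region, pet)
        assert not res.flat_objective
        assert np.linalg.norm(res.translation) <= 0.5

    def test_recovers_8mm_displacement(self, small_grid):
        from histopet.pet_metrics import ellipsoid_region

        pet = self._hot_pet(small_grid, np.array([0.0, 0.0, 0.0]))
        region = ellipsoid_region((8.0, 0, 0), (7, 7, 7), small_grid, 4)
        res = refine_rigid(region, pet)
        assert np.linalg.norm(res.translation - np.array([-8.0, 0, 0])) <= 2.0

    def test_uniform_pet_flags_flat_objective(self, small_grid):
        from histopet.pet_metrics import ellipsoid_region

        pet = make_volume(small_grid, np.full(small_grid.shape, 2.0))
        region = ellipsoid_region((0, 0, 0), (6, 6, 6), small_grid, 4)
        res = refine_rigid(region, pet)
        assert res.flat_objective
        assert res.transform.is_identity
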