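"""Leaflet assignment, density and thickness grids, axial distributions."""

import numpy as np
import pytest

import lipidprint as lp
from lipidprint.core_io import Trajectory
from lipidprint.membrane_geometry import PlanarGrid

from conftest import make_annotated


def _flat_bilayer(n_per_leaflet=8, z=17.5, protein=True):
    """Phosphates on two planes at ±z around a central protein column."""
    prot = [[50.0, 50.0, zz] for zz in np.linspace(35, 65, 7)] if protein else \
        [[50.0, 50.0, 50.0]]
    lips, segs = [], []
    rng = np.random.default_rng(0)
    for sign in (+1, -1):
        for _ in range(n_per_leaflet):
            xy = rng.uniform(20, 80, 2)
            lips.append([xy[0], xy[1], 50.0 + sign * z])
            segs.append("phosphate")
    return make_annotated(prot, lips, segs, box=np.array([100.0, 100.0, 100.0]))


class TestLeaflets:
    def test_two_equal_leaflets(self):
        frame = _flat_bilayer()
        leaf = lp.assign_leaflets(frame)
        uppers = sum(1 for v in leaf.values() if v == "upper")
        assert uppers == len(leaf) - uppers

    def test_flipped_lipid_goes_to_lower(self):
        frame = _flat_bilayer()
        coords = frame.coordinates.copy()
        # move the first upper-leaflet phosphate to the lower plane
        first_lip = np.flatnonzero(frame.segments == "phosphate")[0]
        coords[first_lip, 2] = 50.0 - 17.5
        frame.coordinates = coords
        leaf = lp.assign_leaflets(frame)
        assert leaf[int(frame.molecule_ids[first_lip])] == "lower"

    def test_generator_labels_recovered(self, martini, small_run):
        _, traj, truth = small_run
        ann = lp.classify_particles(traj[0], martini)
        leaf = lp.assign_leaflets(ann)
        agree = sum(leaf[m] == truth.lipid_leaflet[m] for m in truth.lipid_leaflet)
        assert agree == len(truth.lipid_leaflet)

    def test_coplanar_is_an_error(self):
        frame = make_annotated([[0, 0, 0]], [[1, 0, 5], [2, 0, 5]],
                               ["phosphate", "phosphate"], lip_mols=[0, 1])
        with pytest.raises(ValueError, match="coplanar"):
            lp.assign_leaflets(frame)


class TestDensity:
    def test_single_static_lipid_integral_one(self, martini):
        frame = make_annotated([[50, 50, 50]], [[60.0, 60.0, 67.5],
                                                [60.0, 60.0, 32.5]],
                               ["phosphate", "phosphate"], lip_mols=[0, 1])
        traj = Trajectory(frames=[frame] * 10)
        grid = lp.phosphate_density(traj, martini, leaflet="upper",
                                    spacing=1.0, window=(0.0, 1.0))
        assert grid.integral() == pytest.approx(1.0)
        assert np.count_nonzero(grid.values) == 1

    def test_conservation_on_generated_data(self, martini, small_run):
        _, traj, truth = small_run
        n_upper = sum(1 for v in truth.lipid_leaflet.values() if v == "upper")
        for spacing in (1.0, 2.0):
            grid = lp.phosphate_density(traj, martini, leaflet="upper",
                                        spacing=spacing, window=(0.0, 1.0))
            assert grid.integral() == pytest.approx(n_upper, abs=1e-9)

    def test_uniform_random_is_flat_to_poisson(self, martini):
        rng = np.random.default_rng(12)
        frames = []
        n = 400
        for _ in range(5):
            upper = np.column_stack([rng.uniform(0, 64, n),
                                     rng.uniform(0, 64, n),
                                     np.full(n, 67.5)])
            lower = np.column_stack([rng.uniform(0, 64, n),
                                     rng.uniform(0, 64, n),
                                     np.full(n, 32.5)])
            lips = np.vstack([upper, lower])
            frames.append(make_annotated(
                [[32, 32, 50]], lips, ["phosphate"] * (2 * n),
                lip_mols=list(range(2 * n)),
                box=np.array([64.0, 64.0, 100.0])))
        traj = Trajectory(frames=frames)
        grid = lp.phosphate_density(traj, martini, leaflet="upper",
                                    spacing=16.0, window=(0.0, 1.0))
        counts = grid.values * 16.0 ** 2 * len(frames)
        lam = counts.mean()
        # coarse bins hold ~lam counts; all within 5 sigma of Poisson
        assert np.all(np.abs(counts - lam) < 5 * np.sqrt(lam))

    def test_density_grid_rejects_negative(self):
        with pytest.raises(ValueError):
            PlanarGrid(origin=[0, 0], spacing=1.0,
                       values=np.array([[-1.0]]), kind="density")

    def test_grid_text_roundtrip(self, tmp_path):
        g = PlanarGrid(origin=[1.5, -2.0], spacing=0.5,
                       values=np.arange(6, dtype=float).reshape(2, 3),
                       kind="thickness")
        g.write_text(tmp_path / "g.txt")
        back = PlanarGrid.read_text(tmp_path / "g.txt")
        assert np.allclose(back.values, g.values)
        assert back.spacing == g.spacing
        assert back.kind == "thickness"


class TestThickness:
    def test_flat_bilayer_uniform(self, martini):
        traj = Trajectory(frames=[_flat_bilayer(n_per_leaflet=60)] * 5)
        res = lp.thickness_map(traj, martini, spacing=4.0, window=(0.0, 1.0),
                               annulus_cutoff=8.0, bulk_margin=15.0)
        finite = res.grid.values[np.isfinite(res.grid.values)]
        assert np.allclose(finite, 35.0)
        assert res.bulk_thickness == pytest.approx(35.0)
        assert res.annular_thickness == pytest.approx(35.0)

    def test_translation_invariance(self, martini):
        frame = _flat_bilayer(n_per_leaflet=60)
        traj = lambda f: Trajectory(frames=[f] * 3)
        res0 = lp.thickness_map(traj(frame), martini, window=(0.0, 1.0),
                                annulus_cutoff=8.0, bulk_margin=15.0)
        moved = frame.copy()
        moved.coordinates = frame.coordinates + np.array([3.0, -2.0, 7.0])
        moved = make_annotated(
            moved.coordinates[frame.roles == "protein"],
            moved.coordinates[frame.roles == "lipid"],
            list(frame.segments[frame.roles == "lipid"]),
            lip_mols=[m - 1 for m in frame.molecule_ids[frame.roles == "lipid"]],
            box=frame.box)
        res1 = lp.thickness_map(traj(moved), martini, window=(0.0, 1.0),
                                annulus_cutoff=8.0, bulk_margin=15.0)
        assert res1.bulk_thickness == pytest.approx(res0.bulk_thickness)
        assert res1.annular_thickness == pytest.approx(res0.annular_thickness)

    def test_generator_profile_recovered(self, martini):
        from lipidprint.synthetic_data import (AnnulusSpec, BilayerSpec,
                                               SyntheticParams, generate)
        params = SyntheticParams(
            n_frames=200, seed=21,
            bilayer=BilayerSpec(bulk_thickness=50.0, annular_thickness=35.0),
            annulus=AnnulusSpec(n_sites=20, p_occ=0.6))
        traj, _ = generate(params)
        res = lp.thickness_map(traj, martini, window=(0.0, 1.0))
        assert res.bulk_thickness == pytest.approx(50.0, abs=1.0)
        assert res.annular_thickness == pytest.approx(35.0, abs=1.0)

    def test_refinement_consistency(self, martini, small_run):
        """Block-averaging the s/2 grid reproduces the spacing-s density."""
        _, traj, _ = small_run
        coarse = lp.phosphate_density(traj, martini, spacing=4.0,
                                      window=(0.0, 1.0))
        fine = lp.phosphate_density(traj, martini, spacing=2.0,
                                    window=(0.0, 1.0))
        # align the fine grid onto the coarse origin and block-average 2x2
        nx, ny = coarse.values.shape
        assert fine.integral() == pytest.approx(coarse.integral(), abs=1e-9)
        ox = int(round((coarse.origin[0] - fine.origin[0]) / 2.0))
        oy = int(round((coarse.origin[1] - fine.origin[1]) / 2.0))
        total = 0.0
        match = 0
        for i in range(nx):
            for j in range(ny):
                fi, fj = ox + 2 * i, oy + 2 * j
                if 0 <= fi < fine.values.shape[0] - 1 and \
                        0 <= fj < fine.values.shape[1] - 1:
                    block = fine.values[fi:fi + 2, fj:fj + 2].mean()
                    if np.isclose(block, coarse.values[i, j]):
                        match += 1
                    total += 1
        assert match / total > 0.99


class TestAxial:
    def test_single_trp_single_bin(self, martini):
        prot = [[50.0, 50.0, 65.0]]
        frame = make_annotated(prot, [[60, 60, 67.5], [60, 60, 32.5],
                                      [40, 40, 67.4], [40, 40, 32.6]],
                               ["phosphate"] * 4, lip_mols=[0, 1, 2, 3],
                               prot_resnames=["TRP"])
        traj = Trajectory(frames=[frame] * 4)
        hist = lp.axial_distribution(traj, martini, ["TRP"], window=(0.0, 1.0))
        assert hist.counts["TRP"].sum() == 4
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        peak = centers[np.argmax(hist.counts["TRP"])]
        assert peak == pytest.approx(15.0, abs=1.0)

    def test_banded_protein_is_bimodal_inside_bands(self, martini, small_run):
        _, traj, _ = small_run
        hist = lp.axial_distribution(traj, martini, ["ARG", "LYS"],
                                     window=(0.0, 1.0))
        basic = hist.counts["ARG"] + hist.counts["LYS"]
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        upper_peak = centers[centers > 0][np.argmax(basic[centers > 0])]
        lower_peak = centers[centers < 0][np.argmax(basic[centers < 0])]
        # basic residues sit at the two phosphate levels (±17.5 Å)
        assert upper_peak == pytest.approx(17.5, abs=2.5)
        assert lower_peak == pytest.approx(-17.5, abs=2.5)

    def test_four_series_and_missing_type_warns(self, martini, small_run):
        _, traj, _ = small_run
        with pytest.warns(UserWarning, match="HIS"):
            hist = lp.axial_distribution(traj, martini,
                                         ["TRP", "TYR", "ARG", "HIS"],
                                         window=(0.0, 1.0))
        assert set(hist.counts) == {"TRP", "TYR", "ARG", "HIS"}
        assert hist.counts["HIS"].sum() == 0
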