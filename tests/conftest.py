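"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from lipidprint import load_bundled_scheme
from lipidprint.core_io import AnnotatedSystem, heavy_mask
from lipidprint.synthetic_data import (
    AnnulusSpec,
    BilayerSpec,
    SyntheticParams,
    generate,
)


@pytest.fixture(scope="session")
def martini():
    return load_bundled_scheme("martini")


@pytest.fixture(scope="session")
def atomistic():
    return load_bundled_scheme("atomistic")


@pytest.fixture(scope="session")
def small_run(martini):
    """A small seeded synthetic run shared by read-only tests."""
    params = SyntheticParams(
        n_frames=60, seed=7,
        bilayer=BilayerSpec(n_lipids_per_leaflet=30),
        annulus=AnnulusSpec(n_sites=20, p_occ=0.5))
    traj, truth = generate(params)
    return params, traj, truth


def make_annotated(prot_coords, lip_coords, lip_segments, lip_mols=None,
                   box=None, resolution="coarse_grained",
                   prot_resnames=None):
    """Hand-built AnnotatedSystem: protein chain A (one particle per
    residue), lipids chain L grouped by molecule."""
    prot_coords = np.asarray(prot_coords, dtype=float).reshape(-1, 3)
    lip_coords = np.asarray(lip_coords, dtype=float).reshape(-1, 3)
    n_p, n_l = len(prot_coords), len(lip_coords)
    if lip_mols is None:
        lip_mols = list(range(n_l))
    seg_names = {"head_terminal": "NC3", "phosphate": "PO4",
                 "glycerol": "GL1", "tail": "C1A"}
    names = ["BB"] * n_p + [seg_names[s] for s in lip_segments]
    resnames = (list(prot_resnames) if prot_resnames is not None
                else ["LEU"] * n_p) + ["DPPC"] * n_l
    resseqs = list(range(1, n_p + 1)) + [m + 1 for m in lip_mols]
    chains = ["A"] * n_p + ["L"] * n_l
    mols = [0] * n_p + [1 + m for m in lip_mols]
    roles = ["protein"] * n_p + ["lipid"] * n_l
    segments = [""] * n_p + list(lip_segments)
    return AnnotatedSystem(
        coordinates=np.vstack([prot_coords, lip_coords]) if n_p + n_l else
        np.zeros((0, 3)),
        particle_names=np.array(names, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        residue_seqs=np.array(resseqs, dtype=int),
        chain_ids=np.array(chains, dtype=object),
        icodes=np.array([""] * (n_p + n_l), dtype=object),
        molecule_ids=np.array(mols, dtype=int),
        box=box,
        resolution_tag=resolution,
        roles=np.array(roles, dtype=object),
        segments=np.array(segments, dtype=object),
    )


def random_annotated(rng, n_max=500, box_len=50.0, with_box=True):
    """A random mixed protein/lipid system for oracle comparisons."""
    n = int(rng.integers(10, n_max + 1))
    coords = rng.uniform(0, box_len, (n, 3))
    n_p = int(rng.integers(1, n))
    segs = [["head_terminal", "phosphate", "glycerol", "tail"][i]
            for i in rng.integers(0, 4, n - n_p)]
    mols = rng.integers(0, max(1, (n - n_p) // 3 + 1), n - n_p)
    box = np.array([box_len] * 3) if with_box else None
    return make_annotated(coords[:n_p], coords[n_p:], segs,
                          lip_mols=list(mols), box=box)


def brute_force_contacts(frame, params):
    """O(N^2) all-pairs contact oracle, minimum-image when use_pbc."""
    cutoff = params.resolve_cutoff(frame.resolution_tag)
    box = None
    if params.use_pbc:
        box = frame.box
    heavy = heavy_mask(frame)
    pidx = np.flatnonzero((frame.roles == "protein") & heavy)
    lidx = np.flatnonzero((frame.roles == "lipid") & heavy)
    keys = frame.residue_keys()
    best = {}
    for gp in pidx:
        d = frame.coordinates[lidx] - frame.coordinates[gp]
        if box is not None:
            d -= box * np.round(d / box)
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        for j, dd in zip(lidx, dist):
            if dd <= cutoff:
                key = (str(keys[gp]), int(frame.molecule_ids[j]),
                       str(frame.segments[j]))
                if key not in best or dd < best[key]:
                    best[key] = float(dd)
    return best


def contact_dict(contact_set):
    return {(c.residue_key, c.lipid_molecule, c.segment): c.distance
            for c in contact_set.pairs}
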