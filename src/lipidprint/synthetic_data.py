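"""Seeded synthetic membrane-protein/lipid trajectories with known ground truth.

The generator emulates the geometry and occupancy statistics of a
coarse-grained membrane simulation — a roughly cylindrical multi-chain
protein spanning a two-leaflet bilayer in a periodic box, with annular
binding sites on the protein rim whose lipids exchange stochastically with
bulk lipids — without any force-field physics.  Frames are independent (or
Markov-correlated only through site occupancy); there are no inertial
dynamics.  That is sufficient to exercise every occupancy-based statistic
this package computes, which is all the analyses measure.

Ground truth (per-site occupancy series, per-lipid leaflet and contact
series, the analytic thickness profile) is returned alongside the
trajectory, and :func:`ground_truth_expectations` gives the closed-form
values tests assert against.

The leaflet-to-leaflet phosphate distance follows a radial profile that
stays at the annular value across the annulus and relaxes exponentially to
the bulk value outside it::

    t(r) = annular                                          r <= R + w
    t(r) = bulk - (bulk - annular) * exp(-(r - R - w)/lam)  r >  R + w

with R the protein radius, w the annulus width and lam the thinning length
scale, emulating the local bilayer thinning that relieves hydrophobic
mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core_io import MolecularSystem, Trajectory, residue_key

__all__ = [
    "ProteinSpec",
    "BilayerSpec",
    "AnnulusSpec",
    "SyntheticParams",
    "GroundTruth",
    "generate",
    "ground_truth_expectations",
    "thickness_profile",
    "synthetic_crystal_tetramer",
    "params_from_yaml",
    "params_to_yaml",
]

_BASIC = ("ARG", "LYS")
_AROMATIC = ("TRP", "TYR")
_HEAD_NAMES = {"PC": "NC3", "PE": "NH3"}


@dataclass
class ProteinSpec:
    """A rigid pseudo-protein: n_chains sectors of a cylinder wall, each
    carrying residues on an angular-column x z-row lattice."""

    n_chains: int = 4
    residues_per_chain: int = 60
    radius: float = 12.0        # Å, cylinder wall radius
    span: float = 50.0          # Å, z extent
    particles_per_residue: int = 1
    n_columns: int = 5          # angular columns per chain
    layout: str = "membrane_banded"  # basic at phosphate bands, aromatic at glycerol


@dataclass
class BilayerSpec:
    n_lipids_per_leaflet: int = 60   # includes that leaflet's annular-site lipids
    box: tuple = (120.0, 120.0, 100.0)   # Å
    bulk_thickness: float = 50.0     # Å, P-P far from the protein
    annular_thickness: float = 35.0  # Å, P-P at the protein rim
    thinning_length: float = 5.0     # Å, exponential relaxation scale
    annulus_width: float = 6.0       # Å, flat annular shelf beyond the radius
    bulk_exclusion: float = 10.0     # Å, min lipid distance beyond the radius


@dataclass
class AnnulusSpec:
    """Annular binding sites on the protein rim.  Occupancy is independent
    Bernoulli(p_occ) per frame when p_occ is set, else a two-state Markov
    chain (p_on: off->on, p_off: on->off) started from its stationary law."""

    n_sites: int = 20
    p_occ: float | None = None
    p_on: float = 0.10
    p_off: float = 0.10
    site_offset: float = 2.5    # Å, site radius beyond the protein wall


@dataclass
class SyntheticParams:
    protein: ProteinSpec = field(default_factory=ProteinSpec)
    bilayer: BilayerSpec = field(default_factory=BilayerSpec)
    annulus: AnnulusSpec = field(default_factory=AnnulusSpec)
    lipid_name: str = "DPPC"
    n_frames: int = 100
    jitter: float = 0.3         # Å, Gaussian positional noise on all particles
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.annulus, self.bilayer
        for p in (a.p_on, a.p_off, a.p_occ if a.p_occ is not None else 0.0):
            if not (0.0 <= p <= 1.0):
                raise ValueError("occupancy probabilities must be in [0, 1]")
        if b.bulk_thickness <= 0 or b.annular_thickness <= 0:
            raise ValueError("thicknesses must be positive")
        if b.annular_thickness > b.bulk_thickness:
            raise ValueError("annular thickness cannot exceed bulk thickness")
        if a.n_sites % 2:
            raise ValueError("n_sites must be even (half per leaflet)")
        sites_per_leaflet = a.n_sites // 2
        if sites_per_leaflet > b.n_lipids_per_leaflet:
            raise ValueError("more annular sites than lipids per leaflet")


def thickness_profile(params: SyntheticParams, r) -> np.ndarray:
    """Analytic P-P thickness at radial distance r from the protein axis."""
    b, p = params.bilayer, params.protein
    r = np.asarray(r, dtype=float)
    edge = p.radius + b.annulus_width
    decay = b.bulk_thickness - (b.bulk_thickness - b.annular_thickness) * \
        np.exp(-(r - edge) / b.thinning_length)
    return np.where(r <= edge, b.annular_thickness, decay)


# ---------------------------------------------------------------------------
# protein scaffold
# ---------------------------------------------------------------------------

def _residue_name(z: float, params: SyntheticParams, index: int) -> str:
    """Banded layout: basic residues at the phosphate levels, aromatics at
    the glycerol levels (4 Å inside), leucine elsewhere."""
    if params.protein.layout != "membrane_banded":
        return "LEU"
    phos_z = params.bilayer.annular_thickness / 2.0
    if abs(abs(z) - phos_z) <= 2.0:
        return _BASIC[index % 2]
    if abs(abs(z) - (phos_z - 4.0)) <= 2.0:
        return _AROMATIC[index % 2]
    return "LEU"


def _protein_scaffold(params: SyntheticParams):
    """Base (noise-free) protein particle table, centered on the box axis."""
    p = params.protein
    box = np.asarray(params.bilayer.box, dtype=float)
    center = box / 2.0
    sector = 2 * math.pi / p.n_chains
    n_rows = math.ceil(p.residues_per_chain / p.n_columns)
    dz = p.span / n_rows
    coords, names, resnames, resseqs, chains = [], [], [], [], []
    residue_index = 0
    for c in range(p.n_chains):
        chain_id = chr(ord("A") + c)
        for i in range(p.residues_per_chain):
            col = i % p.n_columns
            row = i // p.n_columns
            theta = c * sector + (col + 0.5) / p.n_columns * sector
            z = -p.span / 2 + (row + 0.5) * dz
            base = center + np.array([p.radius * math.cos(theta),
                                      p.radius * math.sin(theta), z])
            resname = _residue_name(z, params, residue_index)
            for k in range(p.particles_per_residue):
                # extra pseudo-particles stack radially outward
                off = np.array([0.8 * k * math.cos(theta),
                                0.8 * k * math.sin(theta), 0.0])
                coords.append(base + off)
                names.append("BB" if k == 0 else f"SC{k}")
                resnames.append(resname)
                resseqs.append(i + 1)
                chains.append(chain_id)
            residue_index += 1
    return (np.asarray(coords), names, resnames, resseqs, chains, center)


def _lipid_template(leaflet: str, head_name: str):
    """Per-particle (name, z-offset from the phosphate) for one lipid;
    the head group points away from the midplane, the tail toward it."""
    sign = 1.0 if leaflet == "upper" else -1.0
    return [(head_name, +3.0 * sign), ("PO4", 0.0), ("GL1", -3.0 * sign),
            ("C1A", -8.0 * sign), ("C2A", -13.0 * sign)]


@dataclass
class GroundTruth:
    site_positions: np.ndarray       # (n_sites, 3) phosphate positions, Å
    site_leaflet: list               # 'upper'/'lower' per site
    site_lipid_molecule: np.ndarray  # molecule id of each site's lipid
    site_nearest_residue: list       # residue key closest to each site
    occupancy: np.ndarray            # (n_frames, n_sites) bool
    lipid_leaflet: dict              # molecule id -> 'upper'/'lower'
    lipid_contact_series: dict       # molecule id -> (n_frames,) bool
    params: SyntheticParams = None


def generate(params: SyntheticParams):
    """Build a seeded trajectory and its ground truth.

    Same seed and params give a bit-identical trajectory.  Raises if the
    requested bulk lipid count cannot be packed outside the exclusion zone
    (bounded rejection sampling).
    """
    rng = np.random.default_rng(params.seed)
    b, a, p = params.bilayer, params.annulus, params.protein
    box = np.asarray(b.box, dtype=float)
    center = box / 2.0
    head_name = _HEAD_NAMES["PE" if params.lipid_name.endswith("PE") else "PC"]

    prot_coords, prot_names, prot_resnames, prot_resseqs, prot_chains, _ = \
        _protein_scaffold(params)
    n_prot = len(prot_coords)

    # --- annular sites -----------------------------------------------------
    r_site = p.radius + a.site_offset
    site_positions, site_leaflet = [], []
    for k in range(a.n_sites):
        theta = 2 * math.pi * (k + 0.5) / a.n_sites
        leaflet = "upper" if k % 2 == 0 else "lower"
        zsign = 1.0 if leaflet == "upper" else -1.0
        z = zsign * thickness_profile(params, r_site) / 2.0
        site_positions.append(center + np.array(
            [r_site * math.cos(theta), r_site * math.sin(theta), float(z)]))
        site_leaflet.append(leaflet)
    site_positions = np.asarray(site_positions)

    prot_keys = [residue_key(c, s) for c, s in zip(prot_chains, prot_resseqs)]
    nearest = []
    for pos in site_positions:
        d = np.linalg.norm(prot_coords - pos, axis=1)
        nearest.append(prot_keys[int(np.argmin(d))])

    # --- lipid bookkeeping -------------------------------------------------
    sites_per_leaflet = a.n_sites // 2
    n_bulk_per_leaflet = b.n_lipids_per_leaflet - sites_per_leaflet
    lipid_leaflets = (["upper"] * sites_per_leaflet + ["lower"] * sites_per_leaflet
                      + ["upper"] * n_bulk_per_leaflet + ["lower"] * n_bulk_per_leaflet)
    # site k (ordered as generated) is served by lipid index: uppers first
    site_lipid_index = []
    up_seen = lo_seen = 0
    for leaflet in site_leaflet:
        if leaflet == "upper":
            site_lipid_index.append(up_seen)
            up_seen += 1
        else:
            site_lipid_index.append(sites_per_leaflet + lo_seen)
            lo_seen += 1
    n_lipids = len(lipid_leaflets)

    # feasibility of bulk packing
    r_excl = p.radius + b.bulk_exclusion
    usable = box[0] * box[1] - math.pi * r_excl ** 2
    if usable < n_bulk_per_leaflet * 45.0:
        raise ValueError("infeasible packing: lipid count exceeds area capacity")

    def bulk_xy():
        for _ in range(10000):
            xy = rng.uniform([0.0, 0.0], box[:2])
            if np.linalg.norm(xy - center[:2]) >= r_excl:
                return xy
        raise ValueError("infeasible packing: rejection sampling exhausted")

    # --- occupancy series --------------------------------------------------
    occ = np.zeros((params.n_frames, a.n_sites), dtype=bool)
    if a.p_occ is not None:
        occ[:] = rng.random((params.n_frames, a.n_sites)) < a.p_occ
    else:
        denom = a.p_on + a.p_off
        stationary = a.p_on / denom if denom > 0 else 0.0
        state = rng.random(a.n_sites) < stationary
        for t in range(params.n_frames):
            occ[t] = state
            u = rng.random(a.n_sites)
            state = np.where(state, u >= a.p_off, u < a.p_on)

    # --- identity arrays (shared across frames) ----------------------------
    names, resnames, resseqs, chains, mol_ids = (list(prot_names),
                                                 list(prot_resnames),
                                                 list(prot_resseqs),
                                                 list(prot_chains), [])
    chain_mol = {chr(ord("A") + c): c for c in range(p.n_chains)}
    mol_ids = [chain_mol[c] for c in prot_chains]
    lipid_mol0 = p.n_chains
    for j in range(n_lipids):
        for name, _ in _lipid_template(lipid_leaflets[j], head_name):
            names.append(name)
            resnames.append(params.lipid_name)
            resseqs.append(j + 1)
            chains.append("L")
            mol_ids.append(lipid_mol0 + j)
    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resseqs = np.asarray(resseqs, dtype=int)
    chains = np.asarray(chains, dtype=object)
    mol_ids = np.asarray(mol_ids, dtype=int)
    icodes = np.full(len(names), "", dtype=object)

    site_lipid_molecule = np.array(
        [lipid_mol0 + site_lipid_index[k] for k in range(a.n_sites)], dtype=int)

    # --- frames ------------------------------------------------------------
    frames = []
    n_particles = n_prot + 5 * n_lipids
    for t in range(params.n_frames):
        coords = np.empty((n_particles, 3))
        coords[:n_prot] = prot_coords
        idx = n_prot
        lipid_xy = np.empty((n_lipids, 2))
        # sites first: occupied lipids sit at their site
        placed = np.zeros(n_lipids, dtype=bool)
        for k in range(a.n_sites):
            j = site_lipid_index[k]
            if occ[t, k]:
                lipid_xy[j] = site_positions[k][:2]
                placed[j] = True
        for j in range(n_lipids):
            if not placed[j]:
                lipid_xy[j] = bulk_xy()
        for j in range(n_lipids):
            r = np.linalg.norm(lipid_xy[j] - center[:2])
            zsign = 1.0 if lipid_leaflets[j] == "upper" else -1.0
            z_phos = center[2] + zsign * thickness_profile(params, r) / 2.0
            for name, dz in _lipid_template(lipid_leaflets[j], head_name):
                coords[idx] = (lipid_xy[j][0], lipid_xy[j][1], z_phos + dz)
                idx += 1
        if params.jitter > 0:
            coords += rng.normal(0.0, params.jitter, coords.shape)
        frames.append(MolecularSystem(
            coordinates=coords, particle_names=names, residue_names=resnames,
            residue_seqs=resseqs, chain_ids=chains, icodes=icodes,
            molecule_ids=mol_ids, box=box.copy(),
            resolution_tag="coarse_grained"))

    lipid_leaflet = {int(lipid_mol0 + j): lipid_leaflets[j] for j in range(n_lipids)}
    contact_series = {int(lipid_mol0 + j): np.zeros(params.n_frames, dtype=bool)
                      for j in range(n_lipids)}
    for k in range(a.n_sites):
        contact_series[int(site_lipid_molecule[k])] = occ[:, k].copy()

    truth = GroundTruth(
        site_positions=site_positions, site_leaflet=site_leaflet,
        site_lipid_molecule=site_lipid_molecule, site_nearest_residue=nearest,
        occupancy=occ, lipid_leaflet=lipid_leaflet,
        lipid_contact_series=contact_series, params=params)
    return Trajectory(frames=frames), truth


def ground_truth_expectations(params: SyntheticParams) -> dict:
    """Closed-form expectations for assertions against measured statistics."""
    a = params.annulus
    if a.p_occ is not None:
        p_stat = a.p_occ
        se = math.sqrt(p_stat * (1 - p_stat) / params.n_frames)
    else:
        denom = a.p_on + a.p_off
        p_stat = a.p_on / denom if denom > 0 else 0.0
        # frames are Markov-correlated; the independent-frame standard error
        # is inflated by the usual autocorrelation factor (1+rho)/(1-rho)
        rho = max(0.0, 1.0 - denom)
        base = p_stat * (1 - p_stat) / params.n_frames
        se = math.sqrt(base * (1 + rho) / (1 - rho)) if rho < 1 else 0.0
    return {
        "stationary_occupancy": p_stat,
        "occupancy_se": se,
        "bulk_thickness": params.bilayer.bulk_thickness,
        "annular_thickness": params.bilayer.annular_thickness,
        "thickness_at": lambda r: thickness_profile(params, r),
        "expected_interacting_mean": a.n_sites * p_stat,
        "residence_variance_zero": a.p_occ in (0.0, 1.0)
        or (a.p_off == 0.0 and a.p_on in (0.0, 1.0)),
    }


# ---------------------------------------------------------------------------
# synthetic crystal stand-ins
# ---------------------------------------------------------------------------

def synthetic_crystal_tetramer(n_lipids: int, pp_distance: float = 35.0,
                               lipid_name: str = "DSPE",
                               seed: int = 0,
                               radius: float = 12.0,
                               span: float = 50.0) -> MolecularSystem:
    """SYNTHETIC stand-in for one tetramer layer of a 2D-crystal structure.

    This is not a deposited structure: it is a constructed tetramer with
    ``n_lipids`` annular lipids ringing the protein wall, phosphates split
    between two planes ``pp_distance`` apart, used to exercise assembly
    expansion, the annular lipid census and the crystal P-P distance
    measurement on inputs with known answers.
    """
    params = SyntheticParams(
        protein=ProteinSpec(radius=radius, span=span),
        bilayer=BilayerSpec(annular_thickness=pp_distance,
                            bulk_thickness=max(pp_distance, 50.0)),
        seed=seed)
    rng = np.random.default_rng(seed)
    prot_coords, prot_names, prot_resnames, prot_resseqs, prot_chains, center = \
        _protein_scaffold(params)
    head_name = _HEAD_NAMES["PE" if lipid_name.endswith("PE") else "PC"]

    coords = list(prot_coords)
    names = list(prot_names)
    resnames = list(prot_resnames)
    resseqs = list(prot_resseqs)
    chains = list(prot_chains)
    r_lip = radius + 2.5
    for j in range(n_lipids):
        theta = 2 * math.pi * (j + 0.5) / n_lipids
        leaflet = "upper" if j % 2 == 0 else "lower"
        zsign = 1.0 if leaflet == "upper" else -1.0
        z_phos = center[2] + zsign * pp_distance / 2.0
        xy = center[:2] + r_lip * np.array([math.cos(theta), math.sin(theta)])
        for name, dz in _lipid_template(leaflet, head_name):
            coords.append(np.array([xy[0], xy[1], z_phos + dz]))
            names.append(name)
            resnames.append(lipid_name)
            resseqs.append(j + 1)
            chains.append("L")
    coords = np.asarray(coords) + rng.normal(0.0, 0.05, (len(coords), 3))

    resnames_arr = np.asarray(resnames, dtype=object)
    resseqs_arr = np.asarray(resseqs, dtype=int)
    chains_arr = np.asarray(chains, dtype=object)
    chain_mol = {c: i for i, c in enumerate(dict.fromkeys(prot_chains))}
    mol_ids = []
    for i in range(len(coords)):
        if chains_arr[i] == "L":
            mol_ids.append(len(chain_mol) + resseqs_arr[i] - 1)
        else:
            mol_ids.append(chain_mol[chains_arr[i]])
    return MolecularSystem(
        coordinates=coords,
        particle_names=np.asarray(names, dtype=object),
        residue_names=resnames_arr,
        residue_seqs=resseqs_arr,
        chain_ids=chains_arr,
        icodes=np.full(len(coords), "", dtype=object),
        molecule_ids=np.asarray(mol_ids, dtype=int),
        box=np.asarray(params.bilayer.box, dtype=float),
        resolution_tag="coarse_grained")


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def params_from_yaml(path) -> SyntheticParams:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    kw = dict(cfg)
    if "protein" in kw:
        kw["protein"] = ProteinSpec(**kw["protein"])
    if "bilayer" in kw:
        bl = dict(kw["bilayer"])
        if "box" in bl:
            bl["box"] = tuple(bl["box"])
        kw["bilayer"] = BilayerSpec(**bl)
    if "annulus" in kw:
        kw["annulus"] = AnnulusSpec(**kw["annulus"])
    return SyntheticParams(**kw)


def params_to_yaml(params: SyntheticParams, path) -> None:
    d = asdict(params)
    d["bilayer"]["box"] = list(d["bilayer"]["box"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
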