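"""Structure and trajectory I/O, particle classification, per-residue export.

The in-memory model is deliberately plain: a :class:`MolecularSystem` is a
flat set of particles (coordinates in Å plus identity fields) with an
optional orthorhombic box, and a :class:`Trajectory` is an ordered list of
systems sharing one topology.  File parsing and writing are delegated to
MDAnalysis; this module is the adapter that resolves alternate locations,
assigns molecule identifiers (one per protein chain, one per lipid/solvent
residue) and rejects inputs the downstream geometry cannot handle
(triclinic boxes).

Lipid particles are classified into four segments — terminal head group
(choline or amine), phosphate, glycerol/ester backbone, acyl tail — by a
:class:`SegmentScheme`, a small text file of ``residue pattern segment``
rules.  The phosphate label is load-bearing: phosphates are the reference
particles for leaflet assignment, density maps, thickness and the
interacting-lipid census.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

__all__ = [
    "MolecularSystem",
    "AnnotatedSystem",
    "Trajectory",
    "SegmentScheme",
    "SEGMENTS",
    "HEADGROUP_SEGMENTS",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_bfactor_pdb",
    "classify_particles",
    "load_bundled_scheme",
    "read_scheme",
    "expand_assembly",
    "residue_key",
    "heavy_mask",
]

SEGMENTS = ("head_terminal", "phosphate", "glycerol", "tail")
#: segments counted as the polar head group; the complement is the tail class
HEADGROUP_SEGMENTS = ("head_terminal", "phosphate", "glycerol")

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "MSE",
}
_WATER_NAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP4", "SPC", "W", "PW"}
_ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "NA+", "CL-", "ION"}

_MARTINI_BEADS = {"BB", "SC1", "SC2", "SC3", "SC4", "PO4", "NC3", "NH3",
                  "GL1", "GL2"}


def residue_key(chain_id: str, residue_seq: int, icode: str = "") -> str:
    """Canonical residue key ``chain:resseq[icode]`` used across all modules."""
    return f"{chain_id}:{residue_seq}{icode.strip()}"


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class MolecularSystem:
    """One frame: particles with identity fields and an optional box (Å)."""

    coordinates: np.ndarray            # (N, 3) float64, Å
    particle_names: np.ndarray         # (N,) str
    residue_names: np.ndarray          # (N,) str
    residue_seqs: np.ndarray           # (N,) int
    chain_ids: np.ndarray              # (N,) str
    icodes: np.ndarray                 # (N,) str
    molecule_ids: np.ndarray           # (N,) int
    box: np.ndarray | None = None      # (3,) orthorhombic lengths, Å
    resolution_tag: str = "atomistic"  # or "coarse_grained"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = len(self.coordinates)
        for attr in ("particle_names", "residue_names", "chain_ids", "icodes"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.residue_seqs = np.asarray(self.residue_seqs, dtype=int)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        for attr in ("particle_names", "residue_names", "residue_seqs",
                     "chain_ids", "icodes", "molecule_ids"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length does not match coordinates")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")
        if self.resolution_tag not in ("atomistic", "coarse_grained"):
            raise ValueError(f"unknown resolution_tag {self.resolution_tag!r}")

    @property
    def n_particles(self) -> int:
        return len(self.coordinates)

    def residue_keys(self) -> np.ndarray:
        """Per-particle residue key ``chain:resseq[icode]``."""
        return np.array(
            [residue_key(c, s, i)
             for c, s, i in zip(self.chain_ids, self.residue_seqs, self.icodes)],
            dtype=object,
        )

    def copy(self) -> "MolecularSystem":
        return replace(
            self,
            coordinates=self.coordinates.copy(),
            particle_names=self.particle_names.copy(),
            residue_names=self.residue_names.copy(),
            residue_seqs=self.residue_seqs.copy(),
            chain_ids=self.chain_ids.copy(),
            icodes=self.icodes.copy(),
            molecule_ids=self.molecule_ids.copy(),
            box=None if self.box is None else self.box.copy(),
        )


@dataclass
class AnnotatedSystem(MolecularSystem):
    """A MolecularSystem plus per-particle role and lipid-segment labels.

    ``roles`` take values in {protein, lipid, solvent, other}; ``segments``
    hold one of the four lipid segments for lipid particles and "" elsewhere.
    """

    roles: np.ndarray = field(default=None)     # (N,) str
    segments: np.ndarray = field(default=None)  # (N,) str, "" for non-lipid

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.roles is None or self.segments is None:
            raise ValueError("AnnotatedSystem requires roles and segments")
        self.roles = np.asarray(self.roles, dtype=object)
        self.segments = np.asarray(self.segments, dtype=object)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; times (ns) optional."""

    frames: list
    frame_times: list | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory needs at least one frame")
        ref = self.frames[0]
        for i, fr in enumerate(self.frames[1:], start=1):
            if fr.n_particles != ref.n_particles:
                raise ValueError(
                    f"frame {i} has {fr.n_particles} particles, "
                    f"frame 0 has {ref.n_particles}"
                )
            for attr in ("particle_names", "residue_names", "residue_seqs",
                         "chain_ids", "molecule_ids"):
                if not np.array_equal(getattr(fr, attr), getattr(ref, attr)):
                    raise ValueError(f"frame {i} topology ({attr}) differs from frame 0")
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != len(self.frames):
                raise ValueError("frame_times length mismatch")
            if np.any(np.diff(t) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


# ---------------------------------------------------------------------------
# segment scheme
# ---------------------------------------------------------------------------

class SchemeError(ValueError):
    pass


@dataclass
class SegmentScheme:
    """Ordered pattern rules mapping (residue, particle) to a lipid segment.

    Rules are ``(residue_name, particle_pattern, segment)`` with fnmatch
    patterns; the first matching rule wins, so specific rules must precede
    broad ones in the scheme file.  ``aliases`` canonicalize residue-name
    dialects (e.g. the PDB chemical-component code to the common name) and
    ``roles`` classify residue names into protein/lipid/solvent/other.
    """

    rules: list = field(default_factory=list)
    aliases: dict = field(default_factory=dict)
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for resname, pattern, segment in self.rules:
            if segment not in SEGMENTS:
                raise SchemeError(f"unknown segment {segment!r} for {resname}/{pattern}")
        for res in self.lipid_residue_names():
            if not any(seg == "phosphate" for rn, _, seg in self.rules if rn == res):
                raise SchemeError(
                    f"lipid residue {res!r} has no phosphate-labeled particle rule"
                )

    def canonical(self, resname: str) -> str:
        return self.aliases.get(resname, resname)

    def lipid_residue_names(self) -> list:
        seen, out = set(), []
        for resname, _, _ in self.rules:
            if resname not in seen:
                seen.add(resname)
                out.append(resname)
        return out

    def role_of(self, resname: str) -> str:
        name = self.canonical(resname)
        if name in self.roles:
            return self.roles[name]
        if name in self.rules_index():
            return "lipid"
        if name in _AMINO_ACIDS:
            return "protein"
        if name in _WATER_NAMES:
            return "solvent"
        return "other"

    def rules_index(self) -> set:
        return {rn for rn, _, _ in self.rules}

    def segment_of(self, resname: str, particle_name: str) -> str | None:
        name = self.canonical(resname)
        for rn, pattern, segment in self.rules:
            if rn == name and fnmatch.fnmatchcase(particle_name, pattern):
                return segment
        return None


def read_scheme(path: str | Path) -> SegmentScheme:
    """Parse a plain-text scheme: ``residue``, ``alias`` and ``role`` lines."""
    rules, aliases, roles = [], {}, {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "alias" and len(parts) == 3:
            aliases[parts[1]] = parts[2]
        elif parts[0] == "role" and len(parts) == 3:
            roles[parts[1]] = parts[2]
        elif parts[0] == "residue" and len(parts) == 4:
            rules.append((parts[1], parts[2], parts[3]))
        else:
            raise SchemeError(f"{path}:{lineno}: cannot parse {raw!r}")
    return SegmentScheme(rules=rules, aliases=aliases, roles=roles)


def load_bundled_scheme(name: str) -> SegmentScheme:
    """Load a scheme shipped with the package.

    Available: ``martini`` (coarse-grained DMPC/DPPC/DSPE bead names) and
    ``atomistic`` (heavy-atom names for the same lipids).
    """
    ref = resources.files("lipidprint.schemes").joinpath(f"{name}.scheme")
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled scheme named {name!r}")
    with resources.as_file(ref) as p:
        return read_scheme(p)


def classify_particles(system: MolecularSystem, scheme: SegmentScheme) -> AnnotatedSystem:
    """Label every particle with a role and, for lipids, one of four segments.

    Raises if the scheme does not cover a lipid-like residue present in the
    system (unknown residue names are never silently skipped) or if a lipid
    molecule carries no phosphate-labeled particle.
    """
    n = system.n_particles
    roles = np.empty(n, dtype=object)
    segments = np.full(n, "", dtype=object)
    unknown: set = set()
    uncovered: set = set()

    for i in range(n):
        resname = scheme.canonical(str(system.residue_names[i]))
        role = scheme.role_of(resname)
        roles[i] = role
        if role == "lipid":
            seg = scheme.segment_of(resname, str(system.particle_names[i]))
            if seg is None:
                uncovered.add((resname, str(system.particle_names[i])))
            else:
                segments[i] = seg
        elif role == "other" and _looks_like_lipid(resname):
            unknown.add(resname)

    if unknown:
        raise SchemeError(
            "scheme does not cover lipid residue name(s): "
            + ", ".join(sorted(unknown))
        )
    if uncovered:
        items = ", ".join(f"{r}/{p}" for r, p in sorted(uncovered))
        raise SchemeError(f"no segment rule matches particle(s): {items}")

    # phosphate is the reference particle: every lipid molecule must have one
    lipid_mask = roles == "lipid"
    if lipid_mask.any():
        for mol in np.unique(system.molecule_ids[lipid_mask]):
            sel = system.molecule_ids == mol
            if not np.any(segments[sel] == "phosphate"):
                resname = system.residue_names[sel][0]
                raise SchemeError(
                    f"lipid molecule {mol} ({resname}) has no phosphate particle"
                )

    return AnnotatedSystem(
        coordinates=system.coordinates,
        particle_names=system.particle_names,
        residue_names=system.residue_names,
        residue_seqs=system.residue_seqs,
        chain_ids=system.chain_ids,
        icodes=system.icodes,
        molecule_ids=system.molecule_ids,
        box=system.box,
        resolution_tag=system.resolution_tag,
        roles=roles,
        segments=segments,
    )


def _looks_like_lipid(resname: str) -> bool:
    """Heuristic for 'this is probably a lipid the scheme forgot'."""
    known_lipid_prefixes = ("DMP", "DPP", "DSP", "POP", "DOP", "DLP", "PE", "PC")
    return any(resname.startswith(p) for p in known_lipid_prefixes)


def heavy_mask(system: MolecularSystem) -> np.ndarray:
    """True for particles that count in contacts: all beads when coarse
    grained, heavy atoms only (hydrogens excluded) when atomistic."""
    if system.resolution_tag == "coarse_grained":
        return np.ones(system.n_particles, dtype=bool)
    out = np.empty(system.n_particles, dtype=bool)
    for i, name in enumerate(system.particle_names):
        s = str(name).strip().lstrip("0123456789")
        out[i] = not s[:1].upper().startswith("H")
    return out


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def _check_box(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    angles = dims[3:6]
    if np.any(np.abs(angles - 90.0) > 1e-3):
        raise ParseError(
            f"triclinic box (angles {angles}) is not supported; "
            "only orthorhombic boxes are handled"
        )
    return dims[:3].copy()


def _universe(path: str | Path, fmt: str | None):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    kwargs = {}
    if fmt is not None:
        kwargs["format"] = fmt
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # MDAnalysis raises assorted types
        raise ParseError(f"{path}: {exc}") from exc


def _attr(ag, name, default):
    try:
        return getattr(ag, name)
    except (AttributeError, mda.exceptions.NoDataError):
        return np.full(len(ag), default, dtype=object)


def _altloc_filter(u) -> np.ndarray:
    """Indices keeping the first alternate location of each atom."""
    ag = u.atoms
    try:
        altlocs = ag.altLocs
    except (AttributeError, mda.exceptions.NoDataError):
        return np.arange(len(ag))
    keep, seen = [], set()
    resids = ag.resids
    names = ag.names
    chains = _attr(ag, "chainIDs", "")
    icodes = _attr(ag, "icodes", "")
    for i in range(len(ag)):
        if not str(altlocs[i]).strip():
            keep.append(i)
            continue
        key = (str(chains[i]), int(resids[i]), str(icodes[i]), str(names[i]))
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return np.asarray(keep, dtype=int)


def _detect_resolution(names: Iterable[str]) -> str:
    hits = sum(1 for n in names if str(n) in _MARTINI_BEADS)
    return "coarse_grained" if hits >= 3 else "atomistic"


def _assign_molecule_ids(resnames, resids, chains, icodes) -> np.ndarray:
    """One molecule per protein chain; one per residue for everything else."""
    n = len(resnames)
    ids = np.empty(n, dtype=int)
    table: dict = {}
    for i in range(n):
        rn = str(resnames[i])
        if rn in _AMINO_ACIDS:
            key = ("chain", str(chains[i]))
        else:
            key = ("res", str(chains[i]), int(resids[i]), str(icodes[i]), rn)
        if key not in table:
            table[key] = len(table)
        ids[i] = table[key]
    return ids


def _system_from_universe(u, resolution: str | None,
                          keep: np.ndarray | None = None) -> MolecularSystem:
    ag = u.atoms
    if keep is None:
        keep = _altloc_filter(u)
    ag = ag[keep]
    names = np.array([str(x) for x in ag.names], dtype=object)
    resnames = np.array([str(x) for x in ag.resnames], dtype=object)
    resids = np.asarray(ag.resids, dtype=int)
    chains = np.array([str(x).strip() for x in _attr(ag, "chainIDs", "")], dtype=object)
    icodes = np.array([str(x).strip() for x in _attr(ag, "icodes", "")], dtype=object)
    box = _check_box(u.dimensions)
    tag = resolution or _detect_resolution(names)
    return MolecularSystem(
        coordinates=np.asarray(ag.positions, dtype=float),
        particle_names=names,
        residue_names=resnames,
        residue_seqs=resids,
        chain_ids=chains,
        icodes=icodes,
        molecule_ids=_assign_molecule_ids(resnames, resids, chains, icodes),
        box=box,
        resolution_tag=tag,
    )


def read_structure(path: str | Path, format: str | None = None,
                   resolution: str | None = None) -> MolecularSystem:
    """Read a PDB or GRO file into a single-frame :class:`MolecularSystem`.

    Alternate locations are resolved deterministically (first kept).  For
    multi-model PDB files only the first model is returned; use
    :func:`read_trajectory` for the frame series.  ``resolution`` forces the
    tag; by default coarse-grained inputs are recognized by bead names.
    """
    u = _universe(path, format)
    return _system_from_universe(u, resolution)


def read_trajectory(path_or_paths, format: str | None = None,
                    resolution: str | None = None,
                    frame_times: Sequence[float] | None = None) -> Trajectory:
    """Read a multi-model PDB or an ordered sequence of GRO/PDB files."""
    if isinstance(path_or_paths, (str, Path)):
        u = _universe(path_or_paths, format)
        keep = _altloc_filter(u)
        frames = []
        for _ in u.trajectory:
            frames.append(_system_from_universe(u, resolution, keep=keep))
        return Trajectory(frames=frames, frame_times=list(frame_times) if frame_times else None)

    frames = []
    ref = None
    for idx, p in enumerate(path_or_paths):
        sys_i = read_structure(p, format=format, resolution=resolution)
        if ref is not None and sys_i.n_particles != ref.n_particles:
            raise ParseError(
                f"frame {idx} ({p}) has {sys_i.n_particles} particles, "
                f"expected {ref.n_particles}"
            )
        ref = ref or sys_i
        frames.append(sys_i)
    return Trajectory(frames=frames, frame_times=list(frame_times) if frame_times else None)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _universe_from_system(system: MolecularSystem):
    n = system.n_particles
    # residues in order of first appearance
    res_keys = []
    res_index = np.empty(n, dtype=int)
    table: dict = {}
    for i in range(n):
        key = (str(system.chain_ids[i]), int(system.residue_seqs[i]),
               str(system.icodes[i]), str(system.residue_names[i]),
               int(system.molecule_ids[i]))
        if key not in table:
            table[key] = len(table)
            res_keys.append(key)
        res_index[i] = table[key]
    n_res = len(res_keys)
    u = mda.Universe.empty(
        n_atoms=n, n_residues=n_res, n_segments=1,
        atom_resindex=res_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in system.particle_names])
    u.add_TopologyAttr("resnames", [k[3] for k in res_keys])
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr("icodes", [k[2] for k in res_keys])
    u.add_TopologyAttr("chainIDs", [str(x) if str(x) else "A"
                                    for x in system.chain_ids])
    u.add_TopologyAttr("segids", ["SYS"])
    u.add_TopologyAttr("altLocs", [""] * n)
    u.add_TopologyAttr("occupancies", np.ones(n))
    u.add_TopologyAttr("tempfactors", np.zeros(n))
    u.atoms.positions = system.coordinates
    if system.box is not None:
        u.dimensions = [*system.box, 90.0, 90.0, 90.0]
    return u


def write_structure(system: MolecularSystem, path: str | Path) -> None:
    """Write a single frame as PDB or GRO (chosen by file extension)."""
    u = _universe_from_system(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (.pdb) or GRO series.

    For GRO output, ``path`` is treated as a template and one numbered file
    per frame is produced (``name_0000.gro`` ...).
    """
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        u = _universe_from_system(traj.frames[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), multiframe=True, n_atoms=u.atoms.n_atoms) as w:
                for fr in traj.frames:
                    u.atoms.positions = fr.coordinates
                    if fr.box is not None:
                        u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                    w.write(u.atoms)
    else:
        for i, fr in enumerate(traj.frames):
            write_structure(fr, path.with_name(f"{path.stem}_{i:04d}{path.suffix}"))


def write_bfactor_pdb(system: MolecularSystem,
                      values: Mapping[str, float],
                      path: str | Path) -> None:
    """Write a PDB whose B-factor column carries a per-residue value.

    ``values`` is keyed by residue key (``chain:resseq[icode]``); residues
    not listed default to 0.  Values are clipped to [0, 999.99] (the PDB
    column range) and written with two decimals, ready for white-to-red
    coloring of contact frequencies in a molecular viewer.
    """
    for k, v in values.items():
        if not np.isfinite(v):
            raise ValueError(f"value for residue {k} is not finite: {v}")
    keys = system.residue_keys()
    b = np.array([float(values.get(k, 0.0)) for k in keys])
    b = np.clip(b, 0.0, 999.99)
    u = _universe_from_system(system)
    u.atoms.tempfactors = b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# assemblies
# ---------------------------------------------------------------------------

def expand_assembly(system: MolecularSystem,
                    operations: Sequence[tuple]) -> MolecularSystem:
    """Apply rigid-body operations (rotation matrix, translation) to build an
    assembly; molecule ids are re-assigned so each generated copy is distinct.

    ``operations`` is a list of ``(R, t)`` with R a 3x3 matrix and t a
    3-vector in Å.  The identity operation must be included explicitly if
    the input copy is wanted in the output.
    """
    if not operations:
        raise ValueError("need at least one operation")
    parts = []
    offset = 0
    n_mols = int(system.molecule_ids.max()) + 1 if system.n_particles else 0
    for R, t in operations:
        R = np.asarray(R, dtype=float).reshape(3, 3)
        t = np.asarray(t, dtype=float).reshape(3)
        copy = system.copy()
        copy.coordinates = system.coordinates @ R.T + t
        copy.molecule_ids = system.molecule_ids + offset
        offset += n_mols
        parts.append(copy)
    first = parts[0]
    return MolecularSystem(
        coordinates=np.concatenate([p.coordinates for p in parts]),
        particle_names=np.concatenate([p.particle_names for p in parts]),
        residue_names=np.concatenate([p.residue_names for p in parts]),
        residue_seqs=np.concatenate([p.residue_seqs for p in parts]),
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        icodes=np.concatenate([p.icodes for p in parts]),
        molecule_ids=np.concatenate([p.molecule_ids for p in parts]),
        box=first.box,
        resolution_tag=first.resolution_tag,
    )
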