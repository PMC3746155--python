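"""Protein-lipid contact fingerprints.

A contact is residue-level presence/absence per frame: a protein residue is
in contact with a lipid segment in a frame if any heavy particle of the
residue lies within the cutoff of any heavy particle of that segment of the
lipid.  The cutoff convention is 4 Å for atomistic systems and 6 Å for
coarse-grained ones (one CG bead subsumes ~4 heavy atoms, so the larger
interparticle cutoff is the accepted equivalent).  Fingerprints are the
per-residue fractions of analyzed frames with at least one contact,
decomposed into the four lipid segments and the head-group/tail classes,
and are compared across data sources by Pearson correlation.

Crystal structures with resolved lipids yield single-frame 0/1 profiles
through the same machinery, making them directly comparable to simulation
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

from .core_io import (
    AnnotatedSystem,
    HEADGROUP_SEGMENTS,
    MolecularSystem,
    SEGMENTS,
    SegmentScheme,
    Trajectory,
    classify_particles,
    heavy_mask,
)

__all__ = [
    "ContactParams",
    "Contact",
    "ContactSet",
    "ContactProfile",
    "CorrelationResult",
    "frame_contacts",
    "contact_profile",
    "crystal_contact_profile",
    "interacting_lipid_count",
    "correlate_profiles",
    "correlation_matrix",
    "annotate_trajectory",
    "window_slice",
]

DEFAULT_CUTOFFS = {"atomistic": 4.0, "coarse_grained": 6.0}


@dataclass
class ContactParams:
    """Contact-detection parameters.

    cutoff=None selects the resolution default (4 Å atomistic, 6 Å coarse
    grained).  analysis_window is a fractional frame range; the default
    [0.2, 1.0] discards the first fifth of a trajectory as equilibration
    (the 200 ns of a 1 microsecond run).
    """

    cutoff: float | None = None
    use_pbc: bool = False
    analysis_window: tuple = (0.2, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.analysis_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid analysis_window {self.analysis_window}")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def resolve_cutoff(self, resolution_tag: str) -> float:
        if self.cutoff is not None:
            return float(self.cutoff)
        return DEFAULT_CUTOFFS[resolution_tag]


@dataclass(frozen=True)
class Contact:
    residue_key: str
    lipid_molecule: int
    segment: str
    distance: float


@dataclass
class ContactSet:
    frame_index: int
    pairs: list  # of Contact


def window_slice(n_frames: int, window: tuple) -> slice:
    """Frame slice for a fractional analysis window of an n-frame trajectory."""
    lo, hi = window
    start = int(round(lo * n_frames))
    stop = int(round(hi * n_frames))
    if start >= stop:
        raise ValueError(
            f"analysis window {window} selects no frames of {n_frames}"
        )
    return slice(start, stop)


def _min_image_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    d = a - b
    if box is not None:
        d -= box * np.round(d / box)
    return d


def frame_contacts(frame: AnnotatedSystem, params: ContactParams,
                   frame_index: int = 0) -> ContactSet:
    """All (protein residue, lipid molecule, segment) triples within cutoff.

    Heavy particles only for atomistic systems.  With use_pbc, distances are
    minimum-image in the orthorhombic box.  A spatial index prunes the pair
    list; recorded distances use the same explicit minimum-image arithmetic
    as a brute-force evaluation, so results are identical to all-pairs.
    """
    cutoff = params.resolve_cutoff(frame.resolution_tag)
    box = None
    if params.use_pbc:
        if frame.box is None:
            raise ValueError("use_pbc requires a box")
        box = frame.box

    heavy = heavy_mask(frame)
    prot_idx = np.flatnonzero((frame.roles == "protein") & heavy)
    lip_idx = np.flatnonzero((frame.roles == "lipid") & heavy)
    if len(prot_idx) == 0 or len(lip_idx) == 0:
        return ContactSet(frame_index=frame_index, pairs=[])

    pcoords = frame.coordinates[prot_idx]
    lcoords = frame.coordinates[lip_idx]
    if box is not None:
        tree = cKDTree(np.mod(lcoords, box), boxsize=box)
        hits = tree.query_ball_point(np.mod(pcoords, box), r=cutoff * (1 + 1e-9) + 1e-9)
    else:
        tree = cKDTree(lcoords)
        hits = tree.query_ball_point(pcoords, r=cutoff * (1 + 1e-9) + 1e-9)

    res_keys = frame.residue_keys()
    best: dict = {}
    for pi, neighbors in enumerate(hits):
        if not neighbors:
            continue
        gp = prot_idx[pi]
        d = _min_image_delta(lcoords[neighbors], frame.coordinates[gp], box)
        dists = np.sqrt(np.einsum("ij,ij->i", d, d))
        for lj, dist in zip(neighbors, dists):
            if dist > cutoff:
                continue
            gl = lip_idx[lj]
            key = (str(res_keys[gp]), int(frame.molecule_ids[gl]),
                   str(frame.segments[gl]))
            if key not in best or dist < best[key]:
                best[key] = float(dist)
    pairs = [Contact(k[0], k[1], k[2], v) for k, v in sorted(best.items())]
    return ContactSet(frame_index=frame_index, pairs=pairs)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["chain", "resseq", "icode", "resname",
                    *SEGMENTS, "headgroup_fraction", "tail_fraction"]


@dataclass
class ContactProfile:
    """Per-residue contact frequencies decomposed by lipid segment.

    ``data`` is indexed by residue key and carries the four segment-class
    fractions plus the head-group and tail class fractions, all in [0, 1].
    ``is_binary`` marks single-structure 0/1 profiles (crystal contacts) so
    that mixed-scale correlations can be flagged.
    """

    data: pd.DataFrame
    n_frames_analyzed: int
    source_tag: str = ""
    is_binary: bool = False

    def __post_init__(self) -> None:
        frac = self.data[list(SEGMENTS) + ["headgroup_fraction", "tail_fraction"]]
        if ((frac.values < -1e-12) | (frac.values > 1 + 1e-12)).any():
            raise ValueError("contact fractions must lie in [0, 1]")

    @property
    def residue_keys(self) -> pd.Index:
        return self.data.index

    def channel(self, channel: str) -> pd.Series:
        col = {"headgroup": "headgroup_fraction", "tail": "tail_fraction"}.get(
            channel, channel)
        if col not in self.data.columns:
            raise KeyError(f"unknown channel {channel!r}")
        return self.data[col]

    def average_subunits(self) -> "ContactProfile":
        """Average fractions over chains at each aligned residue_seq.

        For a homotetramer this folds the four subunits onto one profile
        keyed ``*:resseq``; residues missing from some chains average over
        the chains where they are present.
        """
        df = self.data.copy()
        grouped = df.groupby("resseq", sort=True)
        cols = list(SEGMENTS) + ["headgroup_fraction", "tail_fraction"]
        out = grouped[cols].mean()
        out.insert(0, "resname", grouped["resname"].first())
        out.insert(0, "icode", "")
        out.insert(0, "resseq", out.index)
        out.insert(0, "chain", "*")
        out.index = pd.Index([f"*:{r}" for r in out["resseq"]], name="residue")
        return ContactProfile(out, self.n_frames_analyzed,
                              source_tag=self.source_tag, is_binary=self.is_binary)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# source_tag={self.source_tag}\t"
                     f"n_frames_analyzed={self.n_frames_analyzed}\t"
                     f"binary={int(self.is_binary)}\n")
            self.data.to_csv(fh, sep="\t", index_label="residue")

    @classmethod
    def from_tsv(cls, path) -> "ContactProfile":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(item.split("=", 1) for item in
                        header.lstrip("# ").strip().split("\t"))
            df = pd.read_csv(fh, sep="\t", index_col="residue",
                             keep_default_na=False,
                             dtype={"chain": str, "icode": str})
        return cls(df, int(meta["n_frames_analyzed"]),
                   source_tag=meta.get("source_tag", ""),
                   is_binary=bool(int(meta.get("binary", 0))))


def annotate_trajectory(traj: Trajectory, scheme: SegmentScheme) -> list:
    """Classify frame 0 and propagate the labels to every frame (shared
    topology makes per-frame classification redundant)."""
    first = traj.frames[0]
    if isinstance(first, AnnotatedSystem):
        return list(traj.frames)
    ann0 = classify_particles(first, scheme)
    out = [ann0]
    for fr in traj.frames[1:]:
        out.append(AnnotatedSystem(
            coordinates=fr.coordinates,
            particle_names=fr.particle_names,
            residue_names=fr.residue_names,
            residue_seqs=fr.residue_seqs,
            chain_ids=fr.chain_ids,
            icodes=fr.icodes,
            molecule_ids=fr.molecule_ids,
            box=fr.box,
            resolution_tag=fr.resolution_tag,
            roles=ann0.roles,
            segments=ann0.segments,
        ))
    return out


def _protein_residue_table(frame: AnnotatedSystem) -> pd.DataFrame:
    keys = frame.residue_keys()
    mask = frame.roles == "protein"
    rows = {}
    for i in np.flatnonzero(mask):
        k = str(keys[i])
        if k not in rows:
            rows[k] = (str(frame.chain_ids[i]), int(frame.residue_seqs[i]),
                       str(frame.icodes[i]), str(frame.residue_names[i]))
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["chain", "resseq", "icode", "resname"])
    df.index.name = "residue"
    return df


def _profile_from_flags(res_table: pd.DataFrame, seg_hits: dict,
                        n_frames: int, source_tag: str,
                        is_binary: bool) -> ContactProfile:
    df = res_table.copy()
    for seg in SEGMENTS:
        counts = seg_hits.get(seg, {})
        df[seg] = [counts.get(k, 0) / n_frames for k in df.index]
    head = seg_hits.get("__head__", {})
    tail = seg_hits.get("__tail__", {})
    df["headgroup_fraction"] = [head.get(k, 0) / n_frames for k in df.index]
    df["tail_fraction"] = [tail.get(k, 0) / n_frames for k in df.index]
    return ContactProfile(df, n_frames, source_tag=source_tag, is_binary=is_binary)


def _accumulate(contacts: ContactSet, seg_hits: dict) -> None:
    per_res_segments: dict = {}
    for c in contacts.pairs:
        per_res_segments.setdefault(c.residue_key, set()).add(c.segment)
    for key, segs in per_res_segments.items():
        for seg in segs:
            seg_hits.setdefault(seg, {})[key] = seg_hits.get(seg, {}).get(key, 0) + 1
        if segs & set(HEADGROUP_SEGMENTS):
            seg_hits.setdefault("__head__", {})[key] = \
                seg_hits.get("__head__", {}).get(key, 0) + 1
        if "tail" in segs:
            seg_hits.setdefault("__tail__", {})[key] = \
                seg_hits.get("__tail__", {}).get(key, 0) + 1


def contact_profile(traj: Trajectory, scheme: SegmentScheme,
                    params: ContactParams | None = None,
                    source_tag: str = "") -> ContactProfile:
    """Per-residue contact frequency over the analysis window of a trajectory."""
    params = params or ContactParams()
    frames = annotate_trajectory(traj, scheme)
    sel = window_slice(len(frames), params.analysis_window)
    analyzed = frames[sel]
    res_table = _protein_residue_table(frames[0])
    seg_hits: dict = {}
    for i, fr in enumerate(analyzed, start=sel.start):
        _accumulate(frame_contacts(fr, params, frame_index=i), seg_hits)
    return _profile_from_flags(res_table, seg_hits, len(analyzed),
                               source_tag, is_binary=False)


def crystal_contact_profile(structure: AnnotatedSystem,
                            params: ContactParams | None = None,
                            source_tag: str = "") -> ContactProfile:
    """0/1 contact indicators from a single lipid-containing structure."""
    params = params or ContactParams(analysis_window=(0.0, 1.0))
    if not np.any(structure.roles == "lipid"):
        raise ValueError("structure contains no lipid molecules")
    res_table = _protein_residue_table(structure)
    seg_hits: dict = {}
    _accumulate(frame_contacts(structure, params), seg_hits)
    return _profile_from_flags(res_table, seg_hits, 1, source_tag, is_binary=True)


def interacting_lipid_count(traj: Trajectory, scheme: SegmentScheme,
                            params: ContactParams | None = None):
    """Per-frame number of interacting lipids and its window mean.

    A lipid counts in a frame iff at least one of its phosphate particles is
    within the cutoff of any protein particle (the phosphate-within-6-Å
    convention at coarse-grained resolution).
    """
    params = params or ContactParams()
    frames = annotate_trajectory(traj, scheme)
    first = frames[0]
    cutoff = params.resolve_cutoff(first.resolution_tag)
    if not np.any(first.segments == "phosphate"):
        raise ValueError("no phosphate-labeled particles")
    sel = window_slice(len(frames), params.analysis_window)
    counts = []
    for fr in frames[sel]:
        box = None
        if params.use_pbc:
            if fr.box is None:
                raise ValueError("use_pbc requires a box")
            box = fr.box
        prot_idx = np.flatnonzero((fr.roles == "protein") & heavy_mask(fr))
        phos_idx = np.flatnonzero(fr.segments == "phosphate")
        pcoords = fr.coordinates[prot_idx]
        phcoords = fr.coordinates[phos_idx]
        if box is not None:
            tree = cKDTree(np.mod(pcoords, box), boxsize=box)
            hits = tree.query_ball_point(np.mod(phcoords, box),
                                         r=cutoff * (1 + 1e-9) + 1e-9)
        else:
            tree = cKDTree(pcoords)
            hits = tree.query_ball_point(phcoords, r=cutoff * (1 + 1e-9) + 1e-9)
        mols = set()
        for j, neigh in enumerate(hits):
            if not neigh:
                continue
            d = _min_image_delta(pcoords[neigh], phcoords[j], box)
            if np.any(np.sqrt(np.einsum("ij,ij->i", d, d)) <= cutoff):
                mols.add(int(fr.molecule_ids[phos_idx[j]]))
        counts.append(len(mols))
    counts = np.asarray(counts, dtype=int)
    return counts, float(counts.mean())


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    n_shared: int
    n_dropped: int
    undefined: bool = False
    mixed_scale: bool = False

    def __float__(self) -> float:
        return self.r


def correlate_profiles(p1: ContactProfile, p2: ContactProfile,
                       channel: str = "headgroup") -> CorrelationResult:
    """Pearson r between the per-residue fraction vectors of two profiles.

    Residues absent from either profile (e.g. unresolved termini) are
    dropped, not zero-filled; their count is reported.  A zero-variance
    vector yields an explicit undefined flag rather than a NaN surprise.
    Correlating a 0/1 crystal profile against simulation fractions is
    permitted and flagged as mixed scale.
    """
    shared = p1.residue_keys.intersection(p2.residue_keys)
    n_dropped = (len(p1.residue_keys) - len(shared)) + (len(p2.residue_keys) - len(shared))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared residues; need >= 3")
    shared = sorted(shared)
    v1 = p1.channel(channel).loc[shared].to_numpy(dtype=float)
    v2 = p2.channel(channel).loc[shared].to_numpy(dtype=float)
    mixed = p1.is_binary != p2.is_binary
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return CorrelationResult(r=float("nan"), n_shared=len(shared),
                                 n_dropped=n_dropped, undefined=True,
                                 mixed_scale=mixed)
    r = float(stats.pearsonr(v1, v2).statistic)
    return CorrelationResult(r=r, n_shared=len(shared), n_dropped=n_dropped,
                             mixed_scale=mixed)


def correlation_matrix(profiles: Sequence[ContactProfile]) -> pd.DataFrame:
    """Pairwise Pearson r: head-group channel in the upper triangle, tail
    channel in the lower triangle, 1.0 on the diagonal."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    tags = [p.source_tag or f"profile_{i}" for i, p in enumerate(profiles)]
    n = len(profiles)
    m = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            channel = "headgroup" if i < j else "tail"
            m[i, j] = correlate_profiles(profiles[i], profiles[j], channel).r
    return pd.DataFrame(m, index=tags, columns=tags)
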