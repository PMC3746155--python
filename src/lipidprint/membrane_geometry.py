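"""Leaflet assignment, in-plane phosphate density, bilayer thickness maps
and axial residue-type distributions.

All fields live on a :class:`PlanarGrid` over the membrane (xy) plane.
Phosphate particles are the reference: the bilayer midplane is the median
phosphate z, leaflets are split by the sign of a lipid's mean phosphate z
about the midplane, and local thickness is the leaflet-to-leaflet
phosphate distance (the P-P distance).  A protein embedded in a thicker
bilayer than its hydrophobic span locally thins the membrane; the
``bulk_thickness``/``annular_thickness`` summaries quantify that
hydrophobic-mismatch response.

Frames are aligned before gridding by removing the protein's xy
center-of-geometry drift (translation only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .contacts import ContactParams, annotate_trajectory, window_slice
from .core_io import AnnotatedSystem, SegmentScheme, Trajectory, heavy_mask

__all__ = [
    "PlanarGrid",
    "ThicknessResult",
    "AxialHistogram",
    "assign_leaflets",
    "phosphate_density",
    "thickness_map",
    "axial_distribution",
]

_BACKBONE_NAMES = {"N", "CA", "C", "O", "BB", "OXT"}


@dataclass
class PlanarGrid:
    """2D field over the membrane plane.

    values[ix, iy] covers the cell [origin + i*spacing, origin + (i+1)*spacing).
    kind is one of density (per Å² per frame), thickness (Å), occupancy.
    """

    origin: np.ndarray      # (2,) Å
    spacing: float          # Å
    values: np.ndarray      # (nx, ny)
    kind: str

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2D array of at least 1x1")
        if self.kind == "density" and np.nanmin(self.values) < 0:
            raise ValueError("density grids must be non-negative")

    def bin_centers(self):
        nx, ny = self.values.shape
        cx = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        cy = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return cx, cy

    def integral(self) -> float:
        return float(np.nansum(self.values) * self.spacing ** 2)

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# origin {self.origin[0]:.6f} {self.origin[1]:.6f}\n")
            fh.write(f"# spacing {self.spacing:.6f}\n")
            fh.write(f"# kind {self.kind}\n")
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def read_text(cls, path) -> "PlanarGrid":
        lines = Path(path).read_text().splitlines()
        origin = np.array(lines[0].split()[2:4], dtype=float)
        spacing = float(lines[1].split()[2])
        kind = lines[2].split()[2]
        values = np.loadtxt(lines[3:], ndmin=2)
        return cls(origin=origin, spacing=spacing, values=values, kind=kind)


def assign_leaflets(frame: AnnotatedSystem) -> dict:
    """Map lipid molecule id -> 'upper'/'lower' by mean phosphate z about the
    midplane (median z of all phosphate particles)."""
    phos = frame.segments == "phosphate"
    if np.count_nonzero(phos) < 2:
        raise ValueError("need at least two phosphate particles")
    z = frame.coordinates[:, 2]
    midplane = float(np.median(z[phos]))
    if np.ptp(z[phos]) == 0:
        raise ValueError("all phosphates are coplanar; cannot split leaflets")
    out = {}
    for mol in np.unique(frame.molecule_ids[phos]):
        zmol = z[(frame.molecule_ids == mol) & phos].mean()
        out[int(mol)] = "upper" if zmol > midplane else "lower"
    return out


def _align_offsets(frames) -> list:
    """xy translation per frame pinning the protein center of geometry to its
    first-frame position."""
    ref = None
    offsets = []
    for fr in frames:
        prot = fr.roles == "protein"
        cog = fr.coordinates[prot][:, :2].mean(axis=0)
        if ref is None:
            ref = cog
        offsets.append(ref - cog)
    return offsets


def _collect_phosphates(frames, leaflet: str | None):
    """Aligned phosphate xy (and z) pooled over frames, split by leaflet."""
    offsets = _align_offsets(frames)
    xy_up, xy_lo, z_up, z_lo = [], [], [], []
    for fr, off in zip(frames, offsets):
        leaf = assign_leaflets(fr)
        phos = np.flatnonzero(fr.segments == "phosphate")
        for i in phos:
            mol = int(fr.molecule_ids[i])
            xy = fr.coordinates[i, :2] + off
            if leaf[mol] == "upper":
                xy_up.append(xy)
                z_up.append(fr.coordinates[i, 2])
            else:
                xy_lo.append(xy)
                z_lo.append(fr.coordinates[i, 2])
    return (np.asarray(xy_up).reshape(-1, 2), np.asarray(z_up),
            np.asarray(xy_lo).reshape(-1, 2), np.asarray(z_lo), offsets)


def _grid_edges(xy: np.ndarray, spacing: float):
    lo = np.floor(xy.min(axis=0) / spacing) * spacing
    hi = np.ceil(xy.max(axis=0) / spacing) * spacing
    hi = np.where(hi <= lo, lo + spacing, hi)
    ex = np.arange(lo[0], hi[0] + spacing / 2, spacing)
    ey = np.arange(lo[1], hi[1] + spacing / 2, spacing)
    return ex, ey


def phosphate_density(traj: Trajectory, scheme: SegmentScheme,
                      leaflet: str = "upper", spacing: float = 1.0,
                      window: tuple = (0.2, 1.0)) -> PlanarGrid:
    """Mean phosphate count per Å² per frame on a 2D grid for one leaflet.

    Normalization is exact by construction: integral() returns the mean
    per-frame phosphate count of the leaflet.
    """
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    frames = annotate_trajectory(traj, scheme)
    frames = frames[window_slice(len(frames), window)]
    xy_up, _, xy_lo, _, _ = _collect_phosphates(frames, leaflet)
    xy = xy_up if leaflet == "upper" else xy_lo
    if len(xy) == 0:
        raise ValueError(f"no phosphates in the {leaflet} leaflet")
    ex, ey = _grid_edges(xy, spacing)
    H, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[ex, ey])
    values = H / (len(frames) * spacing ** 2)
    return PlanarGrid(origin=np.array([ex[0], ey[0]]), spacing=spacing,
                      values=values, kind="density")


@dataclass
class ThicknessResult:
    grid: PlanarGrid
    bulk_thickness: float | None       # Å; None if no qualifying bins
    annular_thickness: float | None    # Å
    n_bulk_bins: int
    n_annular_bins: int


def thickness_map(traj: Trajectory, scheme: SegmentScheme,
                  spacing: float = 2.0, window: tuple = (0.2, 1.0),
                  annulus_cutoff: float | None = None,
                  bulk_margin: float = 20.0) -> ThicknessResult:
    """Local P-P distance on a grid plus bulk/annular summaries.

    Each bin's thickness is the difference of the time-averaged upper- and
    lower-leaflet phosphate z surfaces (nearest-phosphate binning: a bin
    unsampled in one leaflet borrows the nearest sampled bin of that
    leaflet; bins empty in both leaflets are missing).  The annular summary averages bins whose center lies
    within the contact cutoff (6 Å coarse-grained, 4 Å atomistic, or an
    explicit ``annulus_cutoff``) of the protein's xy footprint; the bulk
    summary averages bins farther than ``bulk_margin`` from it.
    """
    frames = annotate_trajectory(traj, scheme)
    frames = frames[window_slice(len(frames), window)]
    cutoff = annulus_cutoff if annulus_cutoff is not None else \
        ContactParams().resolve_cutoff(frames[0].resolution_tag)

    xy_up, z_up, xy_lo, z_lo, offsets = _collect_phosphates(frames, None)
    if len(xy_up) == 0 or len(xy_lo) == 0:
        raise ValueError("both leaflets must contain phosphates")
    allxy = np.vstack([xy_up, xy_lo])
    ex, ey = _grid_edges(allxy, spacing)
    nx, ny = len(ex) - 1, len(ey) - 1

    def surface(xy, z):
        sums = np.zeros((nx, ny))
        cnts = np.zeros((nx, ny))
        ix = np.clip(((xy[:, 0] - ex[0]) / spacing).astype(int), 0, nx - 1)
        iy = np.clip(((xy[:, 1] - ey[0]) / spacing).astype(int), 0, ny - 1)
        np.add.at(sums, (ix, iy), z)
        np.add.at(cnts, (ix, iy), 1)
        with np.errstate(invalid="ignore"):
            return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan), cnts

    up, up_n = surface(xy_up, z_up)
    lo, lo_n = surface(xy_lo, z_lo)

    # nearest-phosphate binning: a bin unsampled in one leaflet borrows the
    # nearest sampled bin of that leaflet; bins empty in both leaflets stay
    # missing.  This keeps the thickness defined where annular lipids of the
    # two leaflets sit at interleaved xy positions.
    cx0 = ex[0] + spacing / 2
    cy0 = ey[0] + spacing / 2
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    all_centers = np.stack([cx0 + gx * spacing, cy0 + gy * spacing],
                           axis=-1).reshape(-1, 2)

    def fill_nearest(surf, counts, where):
        sampled = counts > 0
        if not sampled.any():
            return surf
        src = np.stack([cx0 + gx[sampled] * spacing,
                        cy0 + gy[sampled] * spacing], axis=-1)
        stree = cKDTree(src)
        vals = surf[sampled]
        need = where & ~sampled
        if not need.any():
            return surf
        out = surf.copy()
        _, nn = stree.query(all_centers.reshape(nx, ny, 2)[need])
        out[need] = vals[nn]
        return out

    sampled_any = (up_n > 0) | (lo_n > 0)
    up = fill_nearest(up, up_n, sampled_any)
    lo = fill_nearest(lo, lo_n, sampled_any)
    thick = np.abs(up - lo)
    grid = PlanarGrid(origin=np.array([ex[0], ey[0]]), spacing=spacing,
                      values=thick, kind="thickness")

    # protein xy footprint, aligned (first analyzed frame suffices: the
    # alignment pins the protein in place)
    first = frames[0]
    prot_xy = first.coordinates[(first.roles == "protein") &
                                heavy_mask(first)][:, :2] + offsets[0]
    tree = cKDTree(prot_xy)
    cx, cy = grid.bin_centers()
    centers = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    dist = tree.query(centers)[0].reshape(nx, ny)
    finite = np.isfinite(thick)

    annular = finite & (dist <= cutoff)
    bulk = finite & (dist > bulk_margin)
    ann_val = float(thick[annular].mean()) if annular.any() else None
    bulk_val = float(thick[bulk].mean()) if bulk.any() else None
    if ann_val is None:
        warnings.warn("no bins qualify for the annular summary")
    if bulk_val is None:
        warnings.warn("no bins qualify for the bulk summary")
    return ThicknessResult(grid=grid, bulk_thickness=bulk_val,
                           annular_thickness=ann_val,
                           n_bulk_bins=int(bulk.sum()),
                           n_annular_bins=int(annular.sum()))


@dataclass
class AxialHistogram:
    """Distributions of side-chain z positions (relative to the bilayer
    midplane) per residue type, with the phosphate head-group bands."""

    bin_edges: np.ndarray            # (n+1,) Å
    counts: dict                     # residue type -> (n,) counts
    headgroup_band: tuple            # ((lo, hi) lower leaflet, (lo, hi) upper)

    def to_tsv(self, path) -> None:
        import pandas as pd
        mid = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        df = pd.DataFrame({"z_center": mid, **self.counts})
        with open(path, "w") as fh:
            (lo1, hi1), (lo2, hi2) = self.headgroup_band
            fh.write(f"# headgroup_band {lo1:.3f} {hi1:.3f} {lo2:.3f} {hi2:.3f}\n")
            df.to_csv(fh, sep="\t", index=False)


def axial_distribution(traj: Trajectory, scheme: SegmentScheme,
                       residue_types: list, bin_width: float = 1.0,
                       window: tuple = (0.2, 1.0)) -> AxialHistogram:
    """Histogram of side-chain reference z per residue type.

    The reference particle is the mean position of a residue's non-backbone
    heavy particles (backbone-only residues fall back to all particles).
    z is measured from the per-frame midplane.  The head-group band is the
    mean phosphate z ± one standard deviation, per leaflet.
    """
    frames = annotate_trajectory(traj, scheme)
    frames = frames[window_slice(len(frames), window)]
    first = frames[0]
    prot_types = {str(rn) for rn in first.residue_names[first.roles == "protein"]}
    series: dict = {t: [] for t in residue_types}
    for t in residue_types:
        if t not in prot_types:
            warnings.warn(f"residue type {t} absent from protein; empty series")

    # per-residue particle index lists, once (topology shared across frames)
    keys = first.residue_keys()
    heavy = heavy_mask(first)
    res_particles: dict = {}
    res_type: dict = {}
    for i in np.flatnonzero((first.roles == "protein") & heavy):
        k = str(keys[i])
        res_type[k] = str(first.residue_names[i])
        side = str(first.particle_names[i]) not in _BACKBONE_NAMES
        res_particles.setdefault(k, {"side": [], "all": []})
        res_particles[k]["all"].append(i)
        if side:
            res_particles[k]["side"].append(i)

    phos_band = {"upper": [], "lower": []}
    for fr in frames:
        phos = fr.segments == "phosphate"
        mid = float(np.median(fr.coordinates[phos, 2]))
        leaf = assign_leaflets(fr)
        for i in np.flatnonzero(phos):
            side = leaf[int(fr.molecule_ids[i])]
            phos_band[side].append(fr.coordinates[i, 2] - mid)
        for k, groups in res_particles.items():
            t = res_type[k]
            if t not in series:
                continue
            idx = groups["side"] or groups["all"]
            zref = fr.coordinates[idx, 2].mean() - mid
            series[t].append(zref)

    allz = [z for v in series.values() for z in v]
    for side in phos_band:
        allz.extend(phos_band[side])
    zmin = np.floor(min(allz) / bin_width) * bin_width - bin_width
    zmax = np.ceil(max(allz) / bin_width) * bin_width + bin_width
    edges = np.arange(zmin, zmax + bin_width / 2, bin_width)
    counts = {t: np.histogram(v, bins=edges)[0] if v else
              np.zeros(len(edges) - 1, dtype=int)
              for t, v in series.items()}
    band = []
    for side in ("lower", "upper"):
        z = np.asarray(phos_band[side])
        band.append((float(z.mean() - z.std()), float(z.mean() + z.std())))
    return AxialHistogram(bin_edges=edges, counts=counts,
                          headgroup_band=(band[0], band[1]))
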