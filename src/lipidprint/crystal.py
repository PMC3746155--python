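"""Analyses of lipid-containing crystal structures.

2D electron-crystallography structures of membrane channels resolve the
annular lipids bridging crystal neighbors.  The deposited coordinates hold
one layer of the double-layered lattice; :func:`double_layer_operations`
supplies the rigid operations that build the two-layer (octameric, for a
tetramer) assembly, after which :func:`count_lipid_molecules` gives the
annular lipid census and :func:`phosphate_plane_distance` the
leaflet-to-leaflet P-P distance of one membrane layer.
"""

from __future__ import annotations

import numpy as np

from .core_io import (
    AnnotatedSystem,
    MolecularSystem,
    SegmentScheme,
    classify_particles,
    expand_assembly,
)
from .membrane_geometry import assign_leaflets

__all__ = [
    "double_layer_operations",
    "build_double_layer",
    "count_lipid_molecules",
    "phosphate_plane_distance",
]


def double_layer_operations(layer_spacing: float) -> list:
    """Identity plus a two-fold rotation about x dropped by ``layer_spacing``.

    The second operation is a proper rotation (det +1), so chirality is
    preserved; it stacks a flipped copy of the layer below the original,
    the arrangement of a double-layered 2D crystal.
    """
    identity = (np.eye(3), np.zeros(3))
    flip = (np.diag([1.0, -1.0, -1.0]), np.array([0.0, 0.0, -layer_spacing]))
    return [identity, flip]


def build_double_layer(system: MolecularSystem,
                       layer_spacing: float | None = None) -> MolecularSystem:
    """Stack a flipped copy of the layer to form the double-layer assembly.

    By default the spacing is the z extent of the layer plus 10 Å, keeping
    the copies clear of each other.
    """
    if layer_spacing is None:
        z = system.coordinates[:, 2]
        layer_spacing = float(np.ptp(z)) + 10.0
    return expand_assembly(system, double_layer_operations(layer_spacing))


def count_lipid_molecules(system: MolecularSystem | AnnotatedSystem,
                          scheme: SegmentScheme) -> int:
    """Number of distinct lipid molecules resolved in a structure."""
    ann = system if isinstance(system, AnnotatedSystem) else \
        classify_particles(system, scheme)
    mask = ann.roles == "lipid"
    if not mask.any():
        return 0
    return len(np.unique(ann.molecule_ids[mask]))


def phosphate_plane_distance(system: MolecularSystem | AnnotatedSystem,
                             scheme: SegmentScheme | None = None) -> float:
    """Leaflet-to-leaflet P-P distance (Å) of a single membrane layer.

    Lipids are split into leaflets about the median phosphate z; the
    distance is the difference of the leaflet mean phosphate z values.
    """
    ann = system if isinstance(system, AnnotatedSystem) else \
        classify_particles(system, scheme)
    leaf = assign_leaflets(ann)
    phos = ann.segments == "phosphate"
    z = ann.coordinates[:, 2]
    zs = {"upper": [], "lower": []}
    for i in np.flatnonzero(phos):
        zs[leaf[int(ann.molecule_ids[i])]].append(z[i])
    if not zs["upper"] or not zs["lower"]:
        raise ValueError("both leaflets must contain phosphates")
    return float(np.mean(zs["upper"]) - np.mean(zs["lower"]))
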