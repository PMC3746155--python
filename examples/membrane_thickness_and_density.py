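"""Bilayer thickness map, phosphate density, and axial residue bands.

A thick bilayer (bulk P-P distance 50 Å) around a protein whose
hydrophobic span supports only 35 Å: the map shows the membrane thinning
locally to match the protein, the classic hydrophobic-mismatch response.
"""

import numpy as np

import lipidprint as lp
from lipidprint.synthetic_data import AnnulusSpec, BilayerSpec, SyntheticParams, generate

scheme = lp.load_bundled_scheme("martini")
traj, truth = generate(SyntheticParams(
    n_frames=200, seed=11,
    bilayer=BilayerSpec(bulk_thickness=50.0, annular_thickness=35.0),
    annulus=AnnulusSpec(n_sites=20, p_occ=0.6)))

res = lp.thickness_map(traj, scheme, window=(0.0, 1.0))
print(f"Bulk P-P thickness:    {res.bulk_thickness:.1f} Å "
      f"(generator truth 50.0, {res.n_bulk_bins} bins)")
print(f"Annular P-P thickness: {res.annular_thickness:.1f} Å "
      f"(generator truth 35.0, {res.n_annular_bins} bins)")
print("The ~15 Å difference is local thinning at the protein rim.")

grid = lp.phosphate_density(traj, scheme, leaflet="upper", spacing=1.0,
                            window=(0.0, 1.0))
n_upper = sum(1 for v in truth.lipid_leaflet.values() if v == "upper")
print(f"\nUpper-leaflet density integral: {grid.integral():.3f} lipids/frame "
      f"(exactly the {n_upper} upper-leaflet lipids)")
peak = np.unravel_index(np.nanargmax(grid.values), grid.values.shape)
print(f"Highest-density cell: {grid.values[peak]:.3f} Å⁻² — an annular site "
      "where a lipid phosphate is pinned frame after frame.")

hist = lp.axial_distribution(traj, scheme, ["TRP", "TYR", "ARG", "LYS"],
                             window=(0.0, 1.0))
(lo1, hi1), (lo2, hi2) = hist.headgroup_band
print(f"\nHead-group bands (z from midplane): [{lo1:.1f}, {hi1:.1f}] and "
      f"[{lo2:.1f}, {hi2:.1f}] Å")
centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
for t in ("ARG", "TRP"):
    zpk = centers[np.argmax(hist.counts[t])]
    print(f"{t} density peaks at z = {zpk:+.1f} Å — basic side chains sit at "
          "the phosphates, aromatics just below at the glycerol level."
          if t == "ARG" else
          f"{t} density peaks at z = {zpk:+.1f} Å.")
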