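"""Fractional contact times: annular lipids exchange with the bulk.

Each annular site follows a two-state Markov chain, so site lipids are
bound only part of the time; bulk lipids never contact the protein.  The
histogram of per-lipid contact fractions separates the two populations,
and the most-bound lipid's xy trace shows residence at its site
interleaved with bulk excursions.
"""

import numpy as np

import lipidprint as lp
from lipidprint.contacts import ContactParams
from lipidprint.synthetic_data import (AnnulusSpec, BilayerSpec,
                                       SyntheticParams, generate,
                                       ground_truth_expectations)

scheme = lp.load_bundled_scheme("martini")
params = SyntheticParams(
    n_frames=300, seed=5,
    bilayer=BilayerSpec(n_lipids_per_leaflet=40),
    annulus=AnnulusSpec(n_sites=20, p_occ=None, p_on=0.08, p_off=0.12))
traj, truth = generate(params)
exp = ground_truth_expectations(params)

table = lp.lipid_contact_fractions(traj, scheme,
                                   ContactParams(analysis_window=(0.0, 1.0)))
site_fr = table.data.loc[truth.site_lipid_molecule, "contact_fraction"]
print(f"Markov stationary occupancy p_on/(p_on+p_off) = "
      f"{exp['stationary_occupancy']:.3f}")
print(f"Mean measured site contact fraction           = {site_fr.mean():.3f}")
print(f"Lipids with zero contact (bulk population)    = "
      f"{(table.data['contact_fraction'] == 0).sum()} of {len(table.data)}")

print("\nContact-fraction histogram (bin width 0.05):")
for lo, hi, c in zip(table.hist_edges[:-1], table.hist_edges[1:],
                     table.hist_counts):
    if c:
        print(f"  [{lo:.2f}, {hi:.2f}): {'#' * int(c)} {c}")

tr = lp.max_contact_lipid_trace(traj, scheme, table,
                                ContactParams(analysis_window=(0.0, 1.0)))
mol = tr.attrs["molecule_id"]
k = list(truth.site_lipid_molecule).index(mol)
d = np.linalg.norm(tr[["x", "y"]].to_numpy() - truth.site_positions[k][:2],
                   axis=1)
frac = table.data.loc[mol, 'contact_fraction']
print(f"\nMost-bound lipid: molecule {mol}, in contact "
      f"{100 * frac:.0f}% of frames.")
print(f"Its phosphate sits within 2 Å of its site in {np.mean(d < 2):.0%} of "
      f"frames and >10 Å away (bulk excursion) in {np.mean(d > 10):.0%} — "
      "even the tightest lipid exchanges with the bulk.")
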