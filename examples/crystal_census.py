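"""Annular lipid census and P-P distance of a 2D-crystal-style assembly.

Builds a SYNTHETIC stand-in for a lipid-containing 2D-crystal layer (a
tetramer ringed by annular lipids with phosphates on two planes 35 Å
apart), stacks the flipped second layer of the double-layered lattice, and
counts the lipid molecules of the full assembly.  A 0/1 crystal contact
profile is then correlated against a simulation fingerprint.
"""

import lipidprint as lp
from lipidprint.contacts import ContactParams
from lipidprint.synthetic_data import (AnnulusSpec, SyntheticParams,
                                       generate, synthetic_crystal_tetramer)

scheme = lp.load_bundled_scheme("martini")

for name, n_tet in [("72-lipid architecture", 36),
                    ("56-lipid architecture", 28),
                    ("40-lipid architecture", 20)]:
    tet = synthetic_crystal_tetramer(n_tet, pp_distance=35.0)
    octa = lp.build_double_layer(tet)
    census = lp.count_lipid_molecules(octa, scheme)
    pp = lp.phosphate_plane_distance(tet, scheme)
    print(f"{name}: {n_tet} lipids/layer -> {census} in the double layer; "
          f"P-P distance {pp:.1f} Å")

print("\nThe census counts distinct lipid molecules after assembly "
      "expansion; the P-P distance is the leaflet-to-leaflet phosphate "
      "separation of one membrane layer.")

# crystal 0/1 profile vs a simulation fingerprint of the same protein scaffold
tet = synthetic_crystal_tetramer(36, pp_distance=35.0)
ann = lp.classify_particles(tet, scheme)
crystal_prof = lp.crystal_contact_profile(ann, ContactParams(),
                                          source_tag="crystal")
traj, _ = generate(SyntheticParams(n_frames=150, seed=3,
                                   annulus=AnnulusSpec(n_sites=20, p_occ=0.5)))
sim_prof = lp.contact_profile(traj, scheme, ContactParams(),
                              source_tag="simulation")
r = lp.correlate_profiles(crystal_prof, sim_prof, "headgroup")
print(f"\nCrystal-vs-simulation head-group contact correlation: r = {r.r:.2f}"
      f" over {r.n_shared} residues (mixed 0/1-vs-fraction scales "
      f"flagged: {r.mixed_scale}).")
print("Both data sources ring the same protein wall, so residues facing "
      "the annulus score in both; the crystal pins every rim lipid while "
      "the simulation annulus is only half occupied.")
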