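"""Per-residue lipid contact fingerprints and replicate correlations.

Generates two independent synthetic coarse-grained membrane runs with the
same annular-site layout, computes each run's per-residue contact-frequency
profile (6 Å cutoff at coarse-grained resolution), and correlates them.
"""

import lipidprint as lp
from lipidprint.contacts import ContactParams
from lipidprint.synthetic_data import AnnulusSpec, SyntheticParams, generate

scheme = lp.load_bundled_scheme("martini")
params = ContactParams()   # 6 Å CG cutoff, first 20% of frames discarded

profiles = []
for seed in (1, 2):
    traj, truth = generate(SyntheticParams(
        n_frames=150, seed=seed, annulus=AnnulusSpec(n_sites=20, p_occ=0.5)))
    profiles.append(lp.contact_profile(traj, scheme, params,
                                       source_tag=f"replicate_{seed}"))

prof = profiles[0]
top = prof.data.sort_values("headgroup_fraction", ascending=False).head(5)
print("Top head-group contact residues (fraction of analyzed frames in contact):")
print(top[["resname", "headgroup_fraction", "phosphate", "tail"]].round(3))

r = lp.correlate_profiles(profiles[0], profiles[1], "headgroup")
print(f"\nPearson r between replicate head-group fingerprints: {r.r:.3f} "
      f"(over {r.n_shared} residues)")
print("A value near 1 means the same residues face the lipid annulus in "
      "both runs — the fingerprint is a property of the protein surface, "
      "not of one trajectory.")

m = lp.correlation_matrix(profiles)
print("\nCorrelation matrix (head group above diagonal, tails below):")
print(m.round(3))
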