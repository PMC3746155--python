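# lipidprint

Protein–lipid interaction fingerprints for membrane proteins: per-residue
lipid contact profiles from trajectories and lipid-containing crystal
structures, annular-shell statistics (density, thickness, residence times),
residue-type interaction frequencies, and projection of contact
conservation onto a family sequence alignment.

## The problem

A membrane protein is ringed by a first shell of *annular* lipids that
exchange with the bulk bilayer.  Most crystal structures say nothing about
these lipids; a handful of 2D electron-crystallography structures resolve
them directly, and coarse-grained (CG) simulations can predict them.
`lipidprint` makes the two kinds of evidence commensurable and quantifies
the annulus:

- **Contact fingerprint.** For protein residue *i* and cutoff *c* (4 Å for
  atomistic heavy atoms, 6 Å for CG beads — one bead subsumes ~4 heavy
  atoms), the contact fraction is

  f_i = (1/T) Σ_t 1[ min dist(residue i, lipid segment) ≤ c ],

  computed per lipid segment (terminal head group, phosphate, glycerol,
  tail) over the analysis window (default: the last 80% of frames).  A
  crystal structure yields the T = 1 case, a 0/1 indicator profile directly
  comparable to simulation fractions.
- **Fingerprint agreement.** Pearson's *r* between per-residue fraction
  vectors of two data sources (simulation vs crystal, replicate vs
  replicate), per channel (head group / tails).
- **Annulus geometry.** Leaflet assignment about the median phosphate z;
  in-plane phosphate density (mean count Å⁻² frame⁻¹, exactly normalized);
  local bilayer thickness as the leaflet-to-leaflet phosphate (P–P)
  distance on a grid, with bulk and annular summaries — the annular
  thinning of a too-thick bilayer is the hydrophobic-mismatch response.
- **Residence.** Per-lipid fractional contact times, their histogram, and
  the xy trace of the most-bound lipid.
- **Statistics across structures.** Residue-type × lipid-segment
  interaction percentages normalized by residue-type occurrence, axial
  (z) distributions of Trp/Tyr/Arg/Lys, and family-wide contact
  conservation on a supplied multiple sequence alignment.

A seeded synthetic generator (`lipidprint.synthetic_data`) builds toy
membrane-protein/lipid trajectories — a cylindrical multi-chain protein in
a two-leaflet bilayer with annular sites exchanging lipids by a two-state
Markov chain, and an analytic radial thickness profile — with ground truth
for every analysis stage.

## Worked example

```python
import lipidprint as lp
from lipidprint.synthetic_data import SyntheticParams, AnnulusSpec, generate

scheme = lp.load_bundled_scheme("martini")
profiles = []
for seed in (1, 2):
    traj, truth = generate(SyntheticParams(
        n_frames=150, seed=seed, annulus=AnnulusSpec(n_sites=20, p_occ=0.5)))
    profiles.append(lp.contact_profile(traj, scheme, lp.ContactParams(),
                                       source_tag=f"replicate_{seed}"))
r = lp.correlate_profiles(profiles[0], profiles[1], "headgroup")
print(f"r = {r.r:.3f} over {r.n_shared} residues")
```

prints

```
r = 0.989 over 240 residues
```

— the two independent runs agree on which residues face the annulus: the
fingerprint is a property of the protein surface, not of one trajectory.
The same session's thickness analysis (`examples/membrane_thickness_and_density.py`)
prints

```
Bulk P-P thickness:    49.9 Å (generator truth 50.0, 2862 bins)
Annular P-P thickness: 35.0 Å (generator truth 35.0, 64 bins)
```

— the bilayer built 50 Å thick thins to 35 Å against the protein wall.

The `examples/` directory holds one short narrative script per capability
(fingerprints, thickness/density, residence times, crystal census, family
alignment); each prints the numbers it computes and one line on what they
mean.  A thin CLI mirrors the library: `lipidprint contacts`,
`lipidprint thickness`, `lipidprint residence`, `lipidprint simulate`, …
(see `lipidprint --help`).

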