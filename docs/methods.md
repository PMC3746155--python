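# Methods

This note records the models, conventions and numerical choices behind
`lipidprint`, and what its synthetic test beds do and do not establish
about real data.

## Contact model

A contact is **residue-level presence/absence per frame**: protein residue
*i* contacts lipid molecule *m* through segment *s* in frame *t* if any
heavy particle of *i* lies within the cutoff of any heavy particle of *m*
labelled *s*.  We deliberately do not count atomic pairs — presence/absence
makes single-structure (crystal) 0/1 profiles commensurable with
simulation fractions, which is the whole point of the comparison.

- **Cutoffs.** 4 Å for atomistic systems (heavy atoms only; hydrogens are
  excluded because crystal structures generally lack them and the 4 Å
  convention is heavy-atom based), 6 Å for coarse-grained systems (a CG
  bead subsumes ~4 heavy atoms; 6 Å interparticle is the accepted
  equivalent of 4 Å interatomic).  `ContactParams(cutoff=...)` overrides.
- **Analysis window.** Fractional, default `[0.2, 1.0]`: the first fifth
  of any trajectory is treated as equilibration.  Fractional windows apply
  uniformly to trajectories of any length.
- **Neighbor search.** A k-d tree (SciPy `cKDTree`, with `boxsize` for
  minimum-image periodic boundaries in orthorhombic boxes) prunes the pair
  list; distances of surviving candidates are recomputed with the explicit
  minimum-image formula, so results are identical to an all-pairs
  evaluation (the test suite holds the two routes equal on random systems).
  The query radius carries a ~1e-9 relative pad so boundary pairs cannot be
  lost to wrap rounding; the explicit distance filter restores the exact
  `<= cutoff` semantics.  Triclinic boxes are rejected outright: the
  package's minimum-image arithmetic assumes rectangular boxes, and the
  systems it targets are effectively rectangular.
- **Interacting-lipid count.** A lipid counts in a frame iff one of its
  *phosphate* particles is within the cutoff of any protein particle — the
  phosphate is the package-wide reference particle (density, thickness,
  leaflets, counts), and schemes must label one per lipid.

## Profiles and correlations

Per-residue fractions are reported for the four segments plus two classes
(head group = terminal + phosphate + glycerol; tail).  The head-group
class fraction is the fraction of frames with ≥1 contact to *any*
head-group segment, hence ≥ each constituent fraction but ≤ their sum.

Pearson's *r* compares fraction vectors over the residues shared by two
profiles; non-shared residues (unresolved termini) are dropped, never
zero-filled, and the dropped count is reported.  Zero-variance vectors
yield an explicit `undefined` flag instead of a propagating NaN.
Correlating a 0/1 crystal profile with simulation fractions is permitted
and flagged (`mixed_scale`).  For homo-oligomers, profiles may be averaged
over subunits by aligned residue number (`ContactProfile.average_subunits`);
whether to correlate averaged or concatenated per-subunit vectors is
genuinely open — averaged is the default, per-subunit output is retained.
The correlation-matrix layout puts the head-group channel in the upper
triangle and the tail channel in the lower.

## Membrane geometry

- **Midplane and leaflets.** Midplane = median z of all phosphates,
  recomputed per frame (tolerates slow drift); a lipid's leaflet is the
  sign of its mean phosphate z about the midplane.  The median is robust
  for roughly balanced leaflets, which the targeted systems are.
- **Frame alignment.** Translation-only removal of the protein's xy
  center-of-geometry drift before any gridding.  No rotational fit by
  default: for a pseudo-symmetric oligomer a rotation fit is ill-
  conditioned and translation-only is least destructive.
- **Density.** 2D histogram of phosphate xy per leaflet, normalized to
  mean count Å⁻² frame⁻¹; the grid covers all samples, so the integral
  equals the mean per-frame phosphate count exactly, by construction.
  Default spacing 1 Å — fine enough to resolve single-lipid peaks.
- **Thickness.** Per xy-bin difference of the time-averaged upper- and
  lower-leaflet phosphate z surfaces (default spacing 2 Å).  Surfaces use
  nearest-phosphate binning: a bin with no samples in one leaflet borrows
  the nearest sampled bin of that leaflet; bins empty in both leaflets are
  missing.  Without the borrowing rule, thickness would be undefined
  wherever the two leaflets' annular lipids sit at interleaved xy
  positions — exactly the bins the annular summary needs.  The annular
  summary averages bins within the contact cutoff of the protein's xy
  footprint (reusing the contact cutoffs keeps "annular" consistent across
  modules); the bulk summary averages bins farther than a 20 Å margin.
- **Axial distributions.** Side-chain reference = mean of non-backbone
  heavy particles (all particles for backbone-only residues); z measured
  from the per-frame midplane; the head-group band is mean phosphate z ± 1
  SD per leaflet.

## Residence

"Contact time" is fractional occupancy (fraction of analyzed frames in
contact), not a survival analysis — no kinetic rates are fitted.  Binding
events merge gaps of ≤1 frame by default (a single off-frame inside a run
does not split an event; the tolerance is an argument because frame
stride conventions vary).  Histogram bin width 0.05 resolves a ~15%
transient population from a 30–40% annular one.  The max-contact trace
breaks ties to the lowest molecule id and applies the same frame alignment
as the grids so it overlays them.

## Residue-type statistics

Raw score(type, segment) = Σ over residues of that type of the segment
fraction (time-weighted; a `binary` flag switches to ever-contacted).
Scores are divided by the type's occurrence count *in the analyzed
structures* (not a background proteome) and rescaled so each segment
column sums to 100% — percentages are relative propensities within a
segment, stated in the output metadata, since an absolute normalization is
equally defensible.

## Alignment projection

The alignment is always an input (FASTA/Clustal via Biopython); the k-th
non-gap column of a row receives the k-th profile residue's value after a
strict sequence check (first mismatch position reported; an explicit
offset selects a profile window).  Unresolved residues are gap-marked,
never zero-filled.  Family means are over non-gap entries only.
Projection followed by gap-stripping recovers the profile vector exactly.

## Synthetic generator

The generator emulates the *occupancy statistics and geometry* of a CG
membrane simulation, not its physics: a rigid cylindrical pseudo-protein
(4 chains × 60 single-bead residues on a radius-12 Å, span-50 Å lattice)
centered in a 120 × 120 × 100 Å box; two leaflets of 5-bead lipids (head
terminal, phosphate, glycerol, two tail beads); annular sites on the rim
(radius + 2.5 Å) whose dedicated lipids are either at their site or
re-sampled uniformly in the bulk (≥10 Å beyond the protein wall, so an
off-site lipid can never register a contact); independent Bernoulli or
two-state Markov occupancy per site; Gaussian jitter (default σ = 0.3 Å)
on every particle.  Defaults (20 sites, 60 lipids/leaflet, bulk 50 Å /
annular 35 Å) describe a thick bilayer around a 35 Å-span protein — the
regime where annular thinning is visible; set bulk = annular for the
matched-bilayer control.  The banded residue layout (basic residues at the
phosphate levels, aromatics 4 Å below at the glycerol level) makes the
residue-type and axial analyses produce the expected qualitative pattern
on defaults.

The radial P–P profile is

    t(r) = annular                                           r ≤ R + w
    t(r) = bulk − (bulk − annular)·exp(−(r − R − w)/λ)       r > R + w

with annulus width w = 6 Å (the CG contact cutoff, so annular-summary bins
sit on the flat shelf and the generator is self-consistent with its own
ground truth) and thinning length λ = 5 Å, a sub-nanometer relaxation in
line with mismatch-driven deformations.

**What passing tests show — and don't.**  Frames are independent (or
Markov-correlated only through occupancy); there are no inertial dynamics,
no excluded volume among lipids, no protein flexibility, no curvature or
undulations.  Recovery of p, thickness and leaflet labels on this
generator validates the *bookkeeping and estimators*, not force fields or
sampling; numbers measured on real trajectories inherit all the usual MD
caveats.  Markov-correlated occupancies inflate the standard error of the
mean fraction by (1+ρ)/(1−ρ) with ρ = 1 − p_on − p_off;
`ground_truth_expectations` accounts for this.

**Synthetic crystal stand-ins.**  `synthetic_crystal_tetramer` builds a
tetramer layer ringed by a chosen number of annular lipids with phosphates
on two planes a chosen distance apart (jitter σ = 0.05 Å); stacking the
flipped second layer (a proper rotation, chirality preserved) gives the
double-layer assembly of a 2D crystal lattice.  These are constructed
objects with known answers, used to exercise assembly expansion, the lipid
census and the P–P measurement — they are not deposited structures, and
tests on them validate the pipeline, not the depositions.

## Degenerate inputs and tie-breaks

Empty analysis windows, missing boxes under PBC, lipids without phosphate
labels, schemes missing a residue name, all-coplanar phosphates, <3 shared
residues in a correlation, and infeasible lipid packing all raise
immediately with the offending item named.  Minimum-distance ties are
irrelevant (presence/absence semantics); residence ties break to the
lowest molecule id; alternate locations keep the first occurrence;
boundary contacts are inclusive (d = cutoff counts).

## Problem sizes

Test and acceptance runs use 10–500-frame trajectories of 40–120 lipids
(≤ ~900 particles) and 100 random ≤500-particle systems for the
brute-force equivalence check — sizes at which the statistical tolerances
(3σ binomial bands, ±1 Å thickness) are already decisive.

## Known limitations

Orthorhombic boxes only; no XTC/DCD binary trajectories (multi-model PDB
and GRO series cover the text-format scope); GRO files carry no chain
identifiers, so multi-chain residue keys are only unambiguous from PDB
input; no hydrogen-bond detection, curvature, order parameters or
area-per-lipid; no kinetic (k_off) fitting; bundled atomistic schemes
cover common CHARMM-style heavy-atom names with best-effort hydrogen
patterns (hydrogen labels never enter contact statistics, which are
heavy-atom based).
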