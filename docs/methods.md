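# Methods

This note records the models, conventions, numerical choices and known
limitations of dynhelix. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Coordinate model and domain map

A trajectory is an ordered list of frames over a fixed set of monomers; each
monomer stores flat per-particle arrays (names, residue numbers, coordinates,
optional masses/radii). Residue numbering is 1-based human dynamin-2
numbering with no insertion codes, so every residue mentioned in the
literature on this system can be addressed directly. Monomer identity is the
chain id (PDB) or `auth_asym_id` (mmCIF); 56-monomer assemblies are written
as mmCIF because classic PDB chain ids are single characters (≤ 62 chains).
Coarse-grained ensembles are recognized by bead names (`BB`, `SC1`–`SC4` by
default); genotype is inferred from residue 465 (ARG → WT, TRP → R465W).

The `DomainMap` defaults place the G domain at 30–293, the BSE at
1–29 ∪ 294–321 ∪ 698–746, the stalk at 322–499 ∪ 643–697 and the PH domain
at 500–642. These boundaries are reconstructions chosen to be consistent
with the anchor facts of the system: P294/S298/S742/V744/S745 are BSE
residues, residues 330 and 692 flank interface-1, residue 465 lies in stalk
helix αS3, and the G-BSE bend sits at 291–293. The L1N^S loop default
(356–364) is likewise approximate. All ranges are overridable via YAML
config; none of the shipped analyses depend on the exact domain edges except
interface classification, whose 50% domain-majority threshold is itself
configurable.

## Angles

Both inter-domain angles are centroid-defined within one monomer:

* G-BSE: vertex = COM(291–293), V1 → COM(277–285), V2 → COM(299–306).
* BSE-stalk: vertex = COM(315–321 ∪ 702–711) — the two hinge ranges pooled
  into a single centroid, the reading consistent with a single starting
  point for both arms — V3 → COM(30–36 ∪ 170–176), V4 → COM(410–422 ∪
  610–626).

COM weighting defaults to mass-weighted for full-atom monomers and uniform
for coarse-grained beads, whose masses are mapping-scheme-dependent and
often absent from deposited files. Angles are computed per monomer per
frame; the statistical unit everywhere is the per-monomer mean over the
analysis window, which avoids pseudo-replication across autocorrelated
frames. G–G bending asymmetry is Δ = |⟨θ⟩ₐ − ⟨θ⟩ᵦ| over each cross-rung G–G
pair, summarized as mean ± SEM over pairs.

## Analysis windows

Dimer metrics default to the last 10 ns and helix metrics to the last
500 ns, applied through frame time stamps when present; when an ensemble
carries no times, a frame-count window is the fallback (the saving interval
of a given ensemble cannot be recovered from coordinates).

## SASA

Shrake–Rupley with a deterministic generalized-spiral (Fibonacci) point set,
960 points per sphere by default, probe radius 1.4 Å. A surface point is
accessible if it lies outside every neighbor's probe-inflated sphere;
neighbor search is KD-tree based and exact. Isolated-sphere areas are exact
to machine precision by construction (no neighbor test fires); two-sphere
cases agree with a 10⁵-point dense-sampling oracle to well under 2%, and
doubling the point count moves areas by < 0.5%. Rigid-body drift of a dense
cluster's total area is a point-set discretization effect; at 3840
points/sphere it is below 0.1%.

Per-residue SASA is normalized by empirical maximal per-residue values
(theoretical Gly-X-Gly accessibilities), shipped as a user-overridable CSV;
values > 1.5 trigger a table-consistency warning. Coarse-grained beads
default to 2.3 Å radius (typical of 4-to-1 mappings); full-atom radii fall
back to element values. Assembly-context SASA (all other monomers as
occluders) is the default, including for dimers, where the choice between
dimer-context and isolated-monomer SASA is otherwise open.

## Interfaces

A residue is a contact residue when any of its particles lies within 6.0 Å
(inclusive — deterministic at the boundary) of any particle of the partner
monomer; the KD-tree implementation is tested for exact set equality against
an all-pairs oracle. Classification is rule-based because visual/structural
assignment is not reproducible: G–G requires a cross-rung pair with ≥ 50%
G-domain contacts on both sides; interface-1 requires one side ≥ 50% stalk
and the other ≥ 50% BSE; stalk–stalk contacts are interface-2 when they
include residues of the central αS2–αS4 segments (455–495 or 660–690) at
least as often as L1N^S residues, interface-3 when L1N^S dominates, else
unclassified.

Interface area defaults to `exposed_sum` — the summed in-assembly SASA of
the contact residues, the literal reading of "the area included by amino
acids falling within 6 Å" — with a `buried` mode (isolated-monomer SASA
minus in-pair SASA) provided because the phrase is ambiguous; outputs record
which mode produced them. Occupancy of residue r in interface type T is the
fraction of (instance × frame) observations of T whose contact set contains
r; raw counts are kept alongside because the fraction's denominator (frames,
interface copies, or both) is itself a modeling decision.

Hydrogen bonds: donor–acceptor ≤ 3.5 Å; with explicit hydrogens the
D–H···A angle must be ≥ 120°, otherwise a hydrogen-free proxy requires the
antecedent–donor–acceptor angle ≥ 120° (stripped and CG-derived structures
rarely keep hydrogens). Salt bridges: Arg NH1/NH2/NE, Lys NZ, His ND1/NE2
versus Asp OD1/OD2, Glu OE1/OE2 within 4.0 Å, collapsed to one bridge per
residue pair. Both criteria sets are configurable and recorded in output;
charged hydrogen bonds (Lys–Glu) intentionally count in both tallies.

Intra-monomer contacts of a query residue exclude the query and its ±1
sequence neighbors by default (`exclude_neighbors=0` disables this). Note
that the R465 pocket of the wild-type fixture contains E466, a direct
sequence neighbor, so the full literature partner set {N429, Q433, E466,
E468} appears only with the exclusion disabled.

## Helix geometry

The axis is seeded with each principal direction of the monomer-COM cloud
(a flat ring's axis is the *smallest* principal direction) and refined by
Levenberg–Marquardt least squares minimizing the variance of radial
distances; the best of the three seeds wins, and the returned direction is
sign-canonicalized. Along the path order (axial position, then azimuth,
monomer id as tie-break), azimuth steps are folded into [0, 2π) and
accumulated; rung index is the number of completed turns, and consecutive
blocks of four monomers form tetramers. Non-monotone azimuths beyond
tolerance trigger a warning and a robust re-sort by axial position.

Rise per monomer and azimuthal step come from linear fits against path
index; pitch = rise × monomers-per-turn; the helix angle is the pitch angle
arctan(rise / (r·Δφ)) — the angle between the local helical path and the
plane normal to the axis, the standard geometric reading consistent with the
few-degree values reported for these assemblies, which never state an
operational definition. Diameter is twice the mean COM radial distance; an
outer envelope diameter (max particle radial extent) is emitted alongside
since annotated figures often measure the envelope.

## Synthetic assemblies

The generator builds *instrumented scaffolds*, not protein models: ~135
single-bead residues per monomer covering exactly the ranges the analyses
touch. Key constructions:

* Anchor ranges are placed with symmetric spreads about computed centroids,
  so both angles equal their targets exactly (wild-type G-BSE 118°, mutant
  150°, BSE-stalk 109° for all — the study-condition means); targets are
  configurable per spec.
* 56 monomers wind on a cylinder (radius 180 Å, rise 4 Å/monomer,
  14 monomers/turn → pitch 56 Å, four rungs, 14 tetramers). The canonical
  scaffold centroid is subtracted before placement so every monomer's COM
  lies exactly on the cylinder; lattice recovery on noiseless input is then
  limited only by floating point (≪ 0.1%).
* Stalk ends of path neighbors interdigitate within the 6 Å cutoff and
  carry the interface-2 markers (Q474, L478, E482, N487, N489 vs T678 and
  neighbors). Mutant monomers displace these αS segments radially
  (markers +5.5 Å, αS4 cluster −4.5 Å), so marker occupancy stays ≈ 1 in
  the wild-type helix, halves in the intercalated helix (only mutant
  monomers lose it) and collapses in the full-mutant helix.
* Residue 465 is caged (buried) in wild-type monomers and displaced toward
  the neighbor's BSE tip (exposed) in mutants; by construction R465 touches
  P294/V744/S745 of the neighbor BSE and W465 additionally reaches
  S298/S742, and W465's normalized SASA exceeds R465's.
* G-domain contact patches sit half an azimuthal step above and below each
  monomer, so cross-rung G–G pairs join monomers 15 apart along the path —
  in the alternating helix every G–G pair is WT↔mutant, which is what makes
  Δ ≈ 32° there while same-genotype helices give Δ ≈ 0 + noise.
* Full-atom dimers realize 8 cross-monomer hydrogen bonds (two charged) and
  2 salt bridges through a C2-symmetric crisscross interface; `loosened`
  mode (automatic when a mutant is present) shifts the partner 2.5 Å so all
  bonds break and some contact residues drop out.
* The lipid-head nanotube is a cylindrical bead lattice with bead centers on
  the stated outer radius (13.7 nm outer diameter by default).
* Noise is isotropic per-particle Gaussian, i.i.d. per frame, from
  `numpy.random.default_rng(seed)`; generation is byte-deterministic given
  (spec, seed). Frames are stamped 10 ns apart by default so time windows
  behave as on real trajectories.

What the generator does **not** emulate: excluded volume and packing,
internal dynamics and kinetics, bending asymmetry of wild-type G–G pairs
(real helices show Δ ≈ 5–8° from genuine conformational asymmetry; the
scaffold's wild-type Δ is pure noise), calibrated interface areas (scaffold
areas are ~550–650 Å², not the ~1000–1500 Å² of full-residue interfaces),
and the occupancy of T678 in mutant helices (its contact with the
non-displaced 465 pocket survives, unlike the αS2/αS3 markers). Passing
tests therefore demonstrate estimator correctness and sensitivity under
controlled geometry and noise, not force-field realism.

## Statistics

Two recipes, matching how such group comparisons are usually reported:
one-way ANOVA with Tukey HSD, and Kruskal–Wallis with Dunn's rank post-hoc.
Dunn's z uses pooled mean ranks with tie correction
T = Σ(t³−t)/(12(N−1)); the multiplicity adjustment is Holm (conservative,
standard; the choice is open in the source material). Group summaries carry
n, mean, median, quartiles and extremes — the boxplot statistics. Units are
per-monomer (per-tetramer, per-pair) window means; groups containing both
genotypes are split into `<group>.WT` / `<group>.MUT`. ANOVA omnibus
p-values under the null are exactly uniform (verified by a KS check over
1000 resampled runs); 2-group ANOVA reproduces the two-sample t-test.

## Problem sizes and determinism

The shipped verification runs use three 56-monomer helices × 50 frames at
0.5 Å noise for angle statistics, single frames for lattice recovery and
interface snapshots, 200 random assemblies for the contact oracle, and 10⁵
sample points for the SASA oracle; these sizes make the whole suite and the
acceptance script run in well under a minute of compute each while keeping
every recovery margin wide. Re-running any pipeline with the same config
and seed reproduces all CSV outputs byte-identically; figures are optional
and never feed back into analysis.

## Known limitations

* Interface classification thresholds (50% majority, marker segments) are
  deterministic reconstructions of what was originally a visual assignment.
* The contact-based G–G pair definition yields 41 pairs on the generated
  four-rung helix; how the original analysis arrived at n = 16 pairs from
  56 monomers is not recoverable from the text.
* `exposed_sum` areas are not comparable in absolute terms to full-residue
  interface areas; use them for within-study contrasts.
* No dihedral/normal-mode analysis, no energetic scoring, no MD-engine
  binary trajectory readers (convert to multi-model mmCIF first).
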