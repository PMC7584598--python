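# dynhelix

Post-processing toolkit for coordinate ensembles of dynamin-2 oligomers —
the helical GTPase scaffolds that constrict and sever membrane necks during
endocytosis, and whose R465W stalk mutation causes centronuclear myopathy.

Given multi-model mmCIF/PDB ensembles of dimers (full-atom) or 56-monomer
helices (coarse-grained beads), dynhelix computes, per monomer and per frame:

* **Interfaces** — contact residues at a 6 Å minimum-distance cutoff,
  classified into the four dynamin–dynamin interfaces (cross-rung **G–G**,
  stalk/BSE **interface-1**, the central crisscross stalk–stalk
  **interface-2**, and the L1N^S-loop **interface-3**), with interface areas
  and per-residue **occupancy** (fraction of instance × frame observations in
  which a residue participates).
* **SASA** — Shrake–Rupley solvent-accessible surface area with a
  deterministic spiral quadrature, normalized by empirical per-residue
  maximal (Gly-X-Gly) values.
* **Inter-domain angles** — the **G-BSE angle** (vertex at the centroid of
  residues 291–293, arms to centroids of 277–285 and 299–306) and the
  **BSE-stalk angle** (vertex at the pooled hinge centroid 315–321 ∪ 702–711,
  arms to the G-domain core 30–36 ∪ 170–176 and the stalk core
  410–422 ∪ 610–626), plus the **G–G bending asymmetry**
  Δ = |⟨θ⟩ₐ − ⟨θ⟩ᵦ| across cross-rung G–G pairs.
* **Hydrogen bonds / salt bridges** across a full-atom interface
  (donor–acceptor ≤ 3.5 Å with an angle criterion; basic↔acidic groups
  ≤ 4.0 Å, one bridge per residue pair).
* **Helical lattice geometry** — axis fit, diameter, pitch
  (rise per monomer × monomers per turn), pitch angle
  θ = arctan(rise / (r · Δφ)), and per-tetramer radius of gyration
  (56 monomers = 14 tetramers).
* **Group statistics** — one-way ANOVA + Tukey HSD, or Kruskal–Wallis +
  Dunn's test (Holm-adjusted), on per-monomer window means.

Because real microsecond trajectories of such assemblies are rarely shared,
the package ships a deterministic **synthetic-assembly generator**
(`dynhelix.synthetic`) that builds reduced pseudo-dynamin scaffolds with
known ground truth — target angles (wild-type-like 118°, mutant-like 150°),
helix lattice parameters, genotype patterns (all-WT / 28+28 intercalated /
all-mutant), interface contact layouts, and per-frame Gaussian noise — so
every analysis stage is verifiable by parameter recovery.

## Worked example

```python
from dynhelix import synthetic as syn
from dynhelix.geometry import angle_series, g_bse_definition
from dynhelix.stats import compare_groups

groups = {}
for name, pattern, seed in (("WT", "all_wt", 1), ("FM", "all_mutant", 3)):
    traj, truth = syn.build_helix(syn.SyntheticHelixSpec(
        genotype_pattern=pattern, n_frames=20, noise_sigma_A=0.5, seed=seed))
    means = angle_series(traj, g_bse_definition()).window_means()
    groups[name] = means.degrees.to_list()

cmp_ = compare_groups(groups, method="kw_dunn", metric="g_bse_deg")
print(cmp_.summaries[["group", "n", "mean"]])
print(cmp_.pairwise)
```

prints (seeds as above):

```
 group   n        mean
    WT  56  117.974851
    FM  56  149.909207

group_a group_b   p_adjusted
     WT      FM 7.206316e-20
```

i.e. the per-monomer window-mean G-BSE angles recover the 118° (wild-type)
and 150° (mutant, extended BSE) construction targets, and the group contrast
is flagged far below p = 0.001. The `examples/` directory has one short
script per capability (angles and statistics, helix geometry, interfaces and
occupancy, dimer bonds, sequence identity); each prints the numbers it
computes and what they mean.

A thin CLI wraps the same library:

```bash
dynhelix synth helix --pattern alternating --frames 10 --noise 0.5 --seed 2 --out ht.cif
dynhelix analyze --config run.yaml
dynhelix compare --table values.csv --method kw_dunn
```

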