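"""Recover G-BSE angle contrasts across wild-type, hetero and mutant helices.

Builds three 56-monomer helices (all wild type; 28 WT + 28 intercalated
R465W; all mutant) with 0.5 A coordinate noise over 20 frames, measures every
monomer's G-BSE angle per frame, averages per monomer, and compares the
groups with Kruskal-Wallis + Dunn (Holm-adjusted).
"""
from dynhelix import synthetic as syn
from dynhelix.geometry import angle_series, g_bse_definition
from dynhelix.stats import compare_groups

groups = {}
for name, pattern, seed in (("WT", "all_wt", 1), ("HT", "alternating", 2),
                            ("FM", "all_mutant", 3)):
    traj, truth = syn.build_helix(
        syn.SyntheticHelixSpec(genotype_pattern=pattern, n_frames=20,
                               noise_sigma_A=0.5, seed=seed)
    )
    series = angle_series(traj, g_bse_definition())
    means = series.window_means()
    if means.genotype.nunique() > 1:
        for geno, sub in means.groupby("genotype"):
            groups[f"{name}.{'MUT' if geno == 'R465W' else 'WT'}"] = sub.degrees.to_list()
    else:
        groups[name] = means.degrees.to_list()

cmp_ = compare_groups(groups, method="kw_dunn", metric="g_bse_deg")
print(cmp_.summaries[["group", "n", "mean", "median"]].to_string(index=False))
print("\npairwise (Dunn, Holm-adjusted):")
print(cmp_.pairwise.to_string(index=False))
print(
    "\nWild-type-like monomers sit near their 118 degree construction target and"
    "\nmutant-like monomers near 150 degrees; every mutant-vs-WT pair is flagged"
    "\n(p << 0.001) while same-genotype pairs are not."
)
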