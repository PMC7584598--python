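"""Catalog monomer-monomer interfaces in a helix and score residue occupancy.

Contacts use a 6 A minimum-distance cutoff.  In the wild-type helix residue
465 of each monomer touches P294/V744/S745 of its neighbor's BSE; in the
mutant helix the exposed W465 additionally reaches S298/S742, and the
interface-2 markers (Q474, L478, E482, N487, N489, T678) lose occupancy.
"""
from dynhelix import synthetic as syn
from dynhelix.interfaces import (
    catalog_interfaces, occupancy, residue465_bse_interaction,
)
from dynhelix.structures import DomainMap
from dynhelix.topology import assign_topology

dmap = DomainMap()
for pattern in ("all_wt", "all_mutant"):
    traj, _ = syn.build_helix(
        syn.SyntheticHelixSpec(genotype_pattern=pattern, n_frames=4,
                               noise_sigma_A=0.5, seed=6)
    )
    topo = assign_topology(traj.frames[0], (0, 0, 1))
    instances = []
    for frame in traj.frames:
        instances += catalog_interfaces(frame, topo, dmap, compute_area=False)
    by_type = {}
    for inst in instances:
        by_type.setdefault(inst.itype, []).append(inst)
    print(f"\n{pattern}: interface instances per type per frame:")
    for itype, lst in sorted(by_type.items()):
        print(f"  {itype:4s} {len(lst) / len(traj.frames):6.1f}")
    occ = occupancy(by_type.get("IF2", []))
    markers = [474, 478, 482, 487, 489, 678]
    vals = {r: occ.fractions.get(("IF2", r), 0.0) for r in markers}
    print("  interface-2 occupancy of marker residues:")
    print("   ", {r: round(v, 2) for r, v in vals.items()})
    r465 = residue465_bse_interaction(traj.frames[0], topo, dmap, compute_area=False)
    counts = {}
    nonempty = [i for i in r465 if i.residues_b]
    for inst in nonempty:
        for r in inst.residues_b:
            counts[r] = counts.get(r, 0) + 1
    print("  465->neighbor-BSE contact frequency:",
          {r: round(c / len(nonempty), 2) for r, c in sorted(counts.items())})

print(
    "\nMutant monomers carry their stalk interface segments out of the contact"
    "\nzone, so interface-2 marker occupancy collapses in the full-mutant helix,"
    "\nwhile the exposed W465 gains the BSE contacts S298/S742."
)
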