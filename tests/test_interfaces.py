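import numpy as np
import pytest

from dynhelix import interfaces as ifc
from dynhelix import synthetic as syn
from dynhelix.errors import ResolutionError, SelectionError
from dynhelix.sasa import SasaConfig
from dynhelix.structures import DomainMap, MonomerModel, OligomerFrame
from dynhelix.topology import AssemblyTopology


def brute_force_contacts(frame, a, b, cutoff=6.0):
    """All-pairs distance oracle for contact residues (inclusive cutoff)."""
    ma, mb = frame.monomer(a), frame.monomer(b)
    res_a, res_b = set(), set()
    for i in range(ma.n_atoms):
        for j in range(mb.n_atoms):
            if np.linalg.norm(ma.coords[i] - mb.coords[j]) <= cutoff:
                res_a.add(int(ma.residue_numbers[i]))
                res_b.add(int(mb.residue_numbers[j]))
    return frozenset(res_a), frozenset(res_b)


def _random_monomer(mid, rng, n_res=8, atoms_per_res=3, spread=12.0, offset=(0, 0, 0)):
    coords, nums = [], []
    for r in range(1, n_res + 1):
        center = rng.uniform(-spread, spread, 3) + offset
        for _ in range(atoms_per_res):
            coords.append(center + rng.uniform(-1.5, 1.5, 3))
            nums.append(r)
    return MonomerModel(
        mid,
        atom_names=["BB"] * len(nums),
        residue_names=["ALA"] * len(nums),
        residue_numbers=nums,
        coords=np.array(coords),
    )


def _pair_frame(ma, mb):
    return OligomerFrame(0, [ma, mb], resolution="coarse_grained")


def _line_monomer(mid, points, residues=None, names=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    residues = residues or list(range(1, len(points) + 1))
    order = np.argsort(residues)
    return MonomerModel(
        mid,
        atom_names=["BB"] * len(points),
        residue_names=(names or ["ALA"] * len(points)),
        residue_numbers=[residues[i] for i in order],
        coords=points[order],
    )


class TestFindContactResidues:
    def test_distant_monomers_have_no_contacts(self, rng):
        ma = _random_monomer("A", rng)
        mb = _random_monomer("B", rng, offset=(500, 0, 0))
        assert ifc.find_contact_residues(_pair_frame(ma, mb), "A", "B") == (
            frozenset(),
            frozenset(),
        )

    def test_matches_brute_force_oracle_on_random_assemblies(self):
        rng = np.random.default_rng(12345)
        for trial in range(60):
            ma = _random_monomer("A", rng)
            mb = _random_monomer("B", rng, offset=rng.uniform(-6, 6, 3))
            frame = _pair_frame(ma, mb)
            got = ifc.find_contact_residues(frame, "A", "B")
            assert got == brute_force_contacts(frame, "A", "B"), f"trial {trial}"

    def test_cutoff_is_inclusive_at_exactly_6A(self):
        ma = _line_monomer("A", [(0.0, 0.0, 0.0)])
        mb = _line_monomer("B", [(6.0, 0.0, 0.0), (6.0 + 1e-9, 10.0, 0.0)])
        ca, cb = ifc.find_contact_residues(_pair_frame(ma, mb), "A", "B")
        assert ca == frozenset({1})
        assert cb == frozenset({1})  # second residue sits just outside

    def test_contacts_are_symmetric(self, rng):
        ma = _random_monomer("A", rng)
        mb = _random_monomer("B", rng, offset=(4, 2, 0))
        frame = _pair_frame(ma, mb)
        ca, cb = ifc.find_contact_residues(frame, "A", "B")
        cb2, ca2 = ifc.find_contact_residues(frame, "B", "A")
        assert (ca, cb) == (ca2, cb2)


def _toy_topology(pairs_rungs):
    ids = sorted(pairs_rungs)
    return AssemblyTopology(
        rung_of=dict(pairs_rungs),
        tetramer_of={m: 0 for m in ids},
        within_rung_neighbors={m: [] for m in ids},
        gg_partners=[],
        chain_order=ids,
    )


class TestClassifyInterface:
    def test_cross_rung_g_domain_contacts_are_gg(self, domain_map):
        ma = _line_monomer("A", [(0, 0, 0)], residues=[100])  # g_domain
        mb = _line_monomer("B", [(4, 0, 0)], residues=[110])
        frame = _pair_frame(ma, mb)
        topo = _toy_topology({"A": 0, "B": 1})
        contacts = ifc.find_contact_residues(frame, "A", "B")
        assert ifc.classify_interface(frame, ("A", "B"), topo, domain_map, contacts) == "GG"

    def test_interface2_residue_signature(self, domain_map):
        # the residues that lose occupancy in the mutant helix are IF2 markers
        ma = _line_monomer("A", [(i, 0, 0) for i in range(5)],
                           residues=[474, 478, 482, 487, 489])
        mb = _line_monomer("B", [(0, 3, 0)], residues=[678])
        frame = _pair_frame(ma, mb)
        topo = _toy_topology({"A": 0, "B": 0})
        contacts = ifc.find_contact_residues(frame, "A", "B")
        assert ifc.classify_interface(frame, ("A", "B"), topo, domain_map, contacts) == "IF2"

    def test_interface1_stalk_against_bse(self, domain_map):
        ma = _line_monomer("A", [(0, 0, 0), (2, 0, 0)], residues=[330, 692])  # stalk side
        mb = _line_monomer("B", [(0, 3, 0), (2, 3, 0)], residues=[700, 710])  # bse side
        frame = _pair_frame(ma, mb)
        topo = _toy_topology({"A": 0, "B": 0})
        contacts = ifc.find_contact_residues(frame, "A", "B")
        assert ifc.classify_interface(frame, ("A", "B"), topo, domain_map, contacts) == "IF1"

    def test_l1ns_loop_contacts_are_if3(self, domain_map):
        ma = _line_monomer("A", [(i, 0, 0) for i in range(3)], residues=[356, 358, 360])
        mb = _line_monomer("B", [(1, 3, 0)], residues=[430])
        frame = _pair_frame(ma, mb)
        topo = _toy_topology({"A": 0, "B": 0})
        contacts = ifc.find_contact_residues(frame, "A", "B")
        assert ifc.classify_interface(frame, ("A", "B"), topo, domain_map, contacts) == "IF3"

    def test_empty_contacts_raise(self, domain_map):
        ma = _line_monomer("A", [(0, 0, 0)], residues=[100])
        mb = _line_monomer("B", [(50, 0, 0)], residues=[110])
        frame = _pair_frame(ma, mb)
        with pytest.raises(SelectionError):
            ifc.classify_interface(
                frame, ("A", "B"), _toy_topology({"A": 0, "B": 1}), domain_map,
                (frozenset(), frozenset()),
            )


class TestInterfaceArea:
    def test_empty_interface_has_zero_area(self, domain_map):
        inst = ifc.InterfaceInstance(
            pair=("A", "B"), itype="IF2", residues_a=frozenset(), residues_b=frozenset(),
            area_A2=0.0, frame_index=0,
        )
        ma = _line_monomer("A", [(0, 0, 0)])
        mb = _line_monomer("B", [(50, 0, 0)])
        assert ifc.interface_area(_pair_frame(ma, mb), inst) == 0.0

    def test_exposed_sum_equals_per_residue_sasa_sum(self):
        from dynhelix.sasa import residue_sasa

        ma = _line_monomer("A", [(0, 0, 0), (4, 0, 0)])
        mb = _line_monomer("B", [(2, 4, 0)])
        frame = _pair_frame(ma, mb)
        cfg = SasaConfig()
        inst = ifc.InterfaceInstance(
            pair=("A", "B"), itype="IF2",
            residues_a=frozenset({1, 2}), residues_b=frozenset({1}),
            area_A2=0.0, frame_index=0,
        )
        got = ifc.interface_area(frame, inst, cfg)
        want = (
            residue_sasa(frame, "A", 1, cfg).sasa_A2
            + residue_sasa(frame, "A", 2, cfg).sasa_A2
            + residue_sasa(frame, "B", 1, cfg).sasa_A2
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_buried_mode_nonnegative_and_positive_on_contact(self):
        ma = _line_monomer("A", [(0, 0, 0)])
        mb = _line_monomer("B", [(4.0, 0, 0)])
        frame = _pair_frame(ma, mb)
        inst = ifc.InterfaceInstance(
            pair=("A", "B"), itype="IF2",
            residues_a=frozenset({1}), residues_b=frozenset({1}),
            area_A2=0.0, frame_index=0,
        )
        buried = ifc.interface_area(frame, inst, area_mode="buried")
        assert buried > 0.0


class TestOccupancy:
    def _instance(self, residues, itype="IF2", frame=0):
        return ifc.InterfaceInstance(
            pair=("A", "B"), itype=itype,
            residues_a=frozenset(residues), residues_b=frozenset(),
            area_A2=0.0, frame_index=frame,
        )

    def test_hand_counted_fractions(self):
        # 4 instances x 3 frames = 12 observations per interface type
        instances = []
        for f in range(3):
            for k in range(4):
                residues = {474}
                if not (f == 2 and k >= 1):  # 474 missing from 3 of 12
                    residues = {474, 478}
                instances.append(self._instance(residues, frame=f))
        table = ifc.occupancy(instances)
        assert table.observations["IF2"] == 12
        assert table.fractions[("IF2", 474)] == 1.0
        assert table.fractions[("IF2", 478)] == pytest.approx(9 / 12)
        assert table.counts[("IF2", 478)] == 9

    def test_absent_residue_has_no_entry_and_bounds_hold(self):
        table = ifc.occupancy([self._instance({474})])
        assert ("IF2", 999) not in table.fractions
        assert all(0.0 <= v <= 1.0 for v in table.fractions.values())

    def test_no_instances_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="dynhelix.interfaces"):
            table = ifc.occupancy([])
        assert table.fractions == {}
        assert "no interface instances" in caplog.text


def _fa_monomer(mid, atoms):
    """atoms: (residue, resname, atom_name, xyz) tuples, full-atom."""
    atoms = sorted(atoms, key=lambda a: a[0])
    return MonomerModel(
        mid,
        atom_names=[a[2] for a in atoms],
        residue_names=[a[1] for a in atoms],
        residue_numbers=[a[0] for a in atoms],
        coords=np.array([a[3] for a in atoms], dtype=float),
        masses=[12.0] * len(atoms),
    )


class TestHBonds:
    def test_far_apart_is_zero(self):
        ma = _fa_monomer("A", [(10, "SER", "OG", (0, 0, 0)), (10, "SER", "CB", (0, -1.4, 0))])
        mb = _fa_monomer("B", [(20, "GLY", "O", (20, 0, 0))])
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_hbonds(frame, ("A", "B")) == 0

    def test_ser_og_to_backbone_o_with_explicit_hydrogen(self):
        # donor-H...acceptor at 165 degrees, D-A 2.9 A -> one bond
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([2.9, 0.0, 0.0])
        h = d + 0.97 * np.array([np.cos(np.radians(10)), np.sin(np.radians(10)), 0.0])
        ma = _fa_monomer("A", [(10, "SER", "OG", d), (10, "SER", "HG", h),
                               (10, "SER", "CB", (-1.4, 0, 0))])
        mb = _fa_monomer("B", [(20, "GLY", "O", a)])
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_hbonds(frame, ("A", "B")) == 1

    def test_bent_hydrogen_fails_angle(self):
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([2.9, 0.0, 0.0])
        h = d + 0.97 * np.array([0.0, 1.0, 0.0])  # D-H perpendicular: angle(D-H-A) ~ 90
        ma = _fa_monomer("A", [(10, "SER", "OG", d), (10, "SER", "HG", h),
                               (10, "SER", "CB", (-1.4, 0, 0))])
        mb = _fa_monomer("B", [(20, "GLY", "O", a)])
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_hbonds(frame, ("A", "B")) == 0

    def test_hydrogen_free_mode_uses_antecedent_proxy(self):
        ma = _fa_monomer("A", [(10, "SER", "OG", (0, 0, 0)), (10, "SER", "CB", (-1.4, 0, 0))])
        mb = _fa_monomer("B", [(20, "GLY", "O", (2.9, 0, 0))])
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_hbonds(frame, ("A", "B")) == 1
        # antecedent on the acceptor side of the donor: proxy angle fails
        ma2 = _fa_monomer("A", [(10, "SER", "OG", (0, 0, 0)), (10, "SER", "CB", (1.4, 0, 0))])
        frame2 = OligomerFrame(0, [ma2, mb], resolution="full_atom")
        assert ifc.count_hbonds(frame2, ("A", "B")) == 0

    def test_coarse_grained_input_rejected(self, wt_helix):
        traj, _ = wt_helix
        with pytest.raises(ResolutionError):
            ifc.count_hbonds(traj.frames[0], ("M00", "M01"))


class TestSaltBridges:
    def test_lys_glu_at_3p5_counts_once(self):
        ma = _fa_monomer("A", [(10, "LYS", "NZ", (0, 0, 0))])
        mb = _fa_monomer("B", [(20, "GLU", "OE1", (3.5, 0, 0))])
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_salt_bridges(frame, ("A", "B")) == 1

    def test_out_of_range_is_zero(self):
        ma = _fa_monomer("A", [(10, "LYS", "NZ", (0, 0, 0))])
        mb = _fa_monomer("B", [(20, "GLU", "OE1", (8.0, 0, 0))])
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_salt_bridges(frame, ("A", "B")) == 0

    def test_bidentate_arg_asp_collapses_to_one(self):
        ma = _fa_monomer(
            "A",
            [(10, "ARG", "NH1", (0, 0.8, 0)), (10, "ARG", "NH2", (0, -0.8, 0))],
        )
        mb = _fa_monomer(
            "B",
            [(20, "ASP", "OD1", (3.0, 0.8, 0)), (20, "ASP", "OD2", (3.0, -0.8, 0))],
        )
        frame = OligomerFrame(0, [ma, mb], resolution="full_atom")
        assert ifc.count_salt_bridges(frame, ("A", "B")) == 1

    def test_coarse_grained_rejected(self, wt_helix):
        traj, _ = wt_helix
        with pytest.raises(ResolutionError):
            ifc.count_salt_bridges(traj.frames[0], ("M00", "M01"))


class TestResidue465BseInteraction:
    def test_wt_contacts_near_tip_only(self, wt_helix, wt_helix_topology, domain_map):
        traj, _ = wt_helix
        instances = ifc.residue465_bse_interaction(
            traj.frames[0], wt_helix_topology, domain_map, compute_area=False
        )
        nonempty = [i for i in instances if i.residues_b]
        assert nonempty, "expected 465-BSE contacts in the helix"
        for inst in nonempty:
            assert inst.residues_b == frozenset({294, 744, 745})
            assert inst.residues_a == frozenset({465})

    def test_mutant_also_reaches_far_tip(self, mutant_helix, domain_map):
        from dynhelix.topology import assign_topology

        traj, _ = mutant_helix
        topo = assign_topology(traj.frames[0], (0, 0, 1))
        instances = ifc.residue465_bse_interaction(
            traj.frames[0], topo, domain_map, compute_area=False
        )
        nonempty = [i for i in instances if i.residues_b]
        assert nonempty
        for inst in nonempty:
            assert inst.residues_b == frozenset({294, 298, 742, 744, 745})

    def test_displaced_neighbor_gives_empty_instance(self, domain_map):
        mono_a = syn.build_monomer(syn.SyntheticMonomerSpec(), monomer_id="A")
        mono_b = syn.build_monomer(syn.SyntheticMonomerSpec(), monomer_id="B")
        mono_b = mono_b.with_coords(mono_b.coords + np.array([500.0, 0, 0]))
        frame = OligomerFrame(0, [mono_a, mono_b], resolution="coarse_grained")
        topo = AssemblyTopology(
            rung_of={"A": 0, "B": 0}, tetramer_of={"A": 0, "B": 0},
            within_rung_neighbors={"A": ["B"], "B": ["A"]}, gg_partners=[],
            chain_order=["A", "B"],
        )
        instances = ifc.residue465_bse_interaction(frame, topo, domain_map, compute_area=False)
        assert all(not i.residues_b and i.area_A2 == 0.0 for i in instances)


class TestIntramonomerContacts:
    def test_wt_dimer_pocket(self, wt_dimer):
        got = ifc.intramonomer_contacts(wt_dimer, "A", 465)
        assert got == frozenset({429, 433, 468})
        with_neighbors = ifc.intramonomer_contacts(wt_dimer, "A", 465, exclude_neighbors=0)
        assert with_neighbors == frozenset({429, 433, 466, 468})

    def test_mutant_pocket_is_broken(self, fm_dimer):
        assert ifc.intramonomer_contacts(fm_dimer, "A", 465, exclude_neighbors=0) == frozenset()

    def test_isolated_residue_empty_and_missing_raises(self):
        mono = _line_monomer("A", [(0, 0, 0), (50, 0, 0)], residues=[100, 200])
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        assert ifc.intramonomer_contacts(frame, "A", 100) == frozenset()
        with pytest.raises(SelectionError):
            ifc.intramonomer_contacts(frame, "A", 999)

    def test_sequence_neighbor_exclusion(self):
        mono = _line_monomer("A", [(0, 0, 0), (3, 0, 0)], residues=[100, 101])
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        assert ifc.intramonomer_contacts(frame, "A", 100) == frozenset()
        assert ifc.intramonomer_contacts(frame, "A", 100, exclude_neighbors=0) == frozenset({101})


class TestDimerInterface:
    def test_tight_vs_loosened_contact_counts(self):
        tight = syn.build_dimer("WT", "WT", "tight")
        loose = syn.build_dimer("WT", "WT", "loosened")
        ct = ifc.find_contact_residues(tight, "A", "B")
        cl = ifc.find_contact_residues(loose, "A", "B")
        assert len(cl[0]) < len(ct[0]) and len(cl[1]) < len(ct[1])

    def test_bond_counts_drop_when_loosened(self):
        tight = syn.build_dimer("WT", "WT")  # auto -> tight
        loose = syn.build_dimer("WT", "R465W")  # auto -> loosened
        assert ifc.count_hbonds(tight, ("A", "B")) > ifc.count_hbonds(loose, ("A", "B"))
        assert ifc.count_salt_bridges(tight, ("A", "B")) > ifc.count_salt_bridges(
            loose, ("A", "B")
        )
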