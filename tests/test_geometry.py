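import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dynhelix import geometry as geo
from dynhelix import synthetic as syn
from dynhelix.errors import DegenerateGeometryError, SelectionError
from dynhelix.structures import MonomerModel, OligomerFrame, WindowSpec
from dynhelix.topology import AssemblyTopology


def _anchored_monomer(vertex_xyz, arm1_xyz, arm2_xyz):
    """Monomer whose G-BSE anchor ranges have exactly the given centroids.

    Each range gets two beads placed symmetrically about the target point, so
    the uniform center of mass is the target by construction.
    """
    entries = []
    for base, target in ((291, vertex_xyz), (277, arm1_xyz), (299, arm2_xyz)):
        target = np.asarray(target, dtype=float)
        entries.append((base, target + (0.0, 0.0, 1.0)))
        entries.append((base + 1, target - (0.0, 0.0, 1.0)))
    entries.sort()
    return MonomerModel(
        "A",
        atom_names=["BB"] * len(entries),
        residue_names=["ALA"] * len(entries),
        residue_numbers=[e[0] for e in entries],
        coords=np.array([e[1] for e in entries]),
    )


class TestCenterOfMass:
    def test_uniform_mean(self):
        assert np.allclose(
            geo.center_of_mass(np.array([[0.0, 0, 0], [2.0, 0, 0]]), weighting="uniform"),
            (1.0, 0.0, 0.0),
        )

    def test_single_atom_is_identity(self):
        p = np.array([[3.0, -1.0, 2.5]])
        assert np.allclose(geo.center_of_mass(p, weighting="uniform"), p[0])

    def test_mass_weighted_mean(self):
        com = geo.center_of_mass(
            np.array([[0.0, 0, 0], [4.0, 0, 0]]), masses=[1.0, 3.0], weighting="mass"
        )
        assert np.allclose(com, (3.0, 0.0, 0.0))

    def test_empty_selection_raises(self):
        with pytest.raises(SelectionError):
            geo.center_of_mass(np.empty((0, 3)))


class TestAngleBetween:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [((1, 0, 0), (0, 1, 0), 90.0), ((1, 0, 0), (1, 0, 0), 0.0)],
    )
    def test_basic_angles(self, v1, v2, expected):
        assert geo.angle_between(v1, v2) == pytest.approx(expected)

    def test_near_antiparallel_clamps_to_180(self):
        assert geo.angle_between((1, 0, 0), (-1, 1e-9, 0)) == pytest.approx(180.0, abs=1e-6)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            geo.angle_between((0, 0, 0), (1, 0, 0))


class TestInterDomainAngles:
    def test_right_angle_from_hand_computed_centroids(self):
        mono = _anchored_monomer((0, 0, 0), (10, 0, 0), (0, 10, 0))
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        assert geo.g_bse_angle(frame, "A") == pytest.approx(90.0, abs=1e-9)

    def test_collinear_anchors_give_180(self):
        mono = _anchored_monomer((0, 0, 0), (10, 0, 0), (-7, 0, 0))
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        assert geo.g_bse_angle(frame, "A") == pytest.approx(180.0, abs=1e-9)

    def test_missing_anchor_residues_reported(self):
        mono = _anchored_monomer((0, 0, 0), (10, 0, 0), (0, 10, 0))
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        with pytest.raises(SelectionError, match="315-321"):
            geo.bse_stalk_angle(frame, "A")

    def test_bse_stalk_union_centroid_right_angle(self):
        # hinge ranges pool to one centroid at the origin; arm unions at the axes
        entries = []
        for res, xyz in (
            (315, (0, 0, 2.0)), (702, (0, 0, -2.0)),       # hinge union -> origin
            (30, (10, 0, 1.0)), (170, (10, 0, -1.0)),      # G core union -> (10,0,0)
            (410, (0, 10, 1.0)), (610, (0, 10, -1.0)),     # stalk union -> (0,10,0)
        ):
            entries.append((res, np.asarray(xyz, dtype=float)))
        entries.sort()
        mono = MonomerModel(
            "A",
            atom_names=["BB"] * len(entries),
            residue_names=["ALA"] * len(entries),
            residue_numbers=[e[0] for e in entries],
            coords=np.array([e[1] for e in entries]),
        )
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        assert geo.bse_stalk_angle(frame, "A") == pytest.approx(90.0, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mono = syn.build_monomer(
            syn.SyntheticMonomerSpec(target_g_bse_deg=float(rng.uniform(20, 160)))
        )
        frame = OligomerFrame(0, [mono], resolution="coarse_grained")
        before = geo.g_bse_angle(frame, "A")
        rot = Rotation.random(random_state=int(seed % 2**16)).as_matrix()
        moved = frame.transformed(rotation=rot, translation=rng.uniform(-100, 100, 3))
        assert geo.g_bse_angle(moved, "A") == pytest.approx(before, abs=1e-6)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert geo.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_two_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert geo.radius_of_gyration(coords) == pytest.approx(1.0)

    def test_matches_loop_based_oracle(self, rng):
        coords = rng.normal(0, 10, size=(100, 3))
        masses = rng.uniform(1, 20, size=100)
        com = sum(m * c for m, c in zip(masses, coords)) / masses.sum()
        acc = sum(m * np.dot(c - com, c - com) for m, c in zip(masses, coords))
        expected = np.sqrt(acc / masses.sum())
        got = geo.radius_of_gyration(coords, masses, weighting="mass")
        assert got == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_scales_linearly_with_coordinates(self, scale):
        rng = np.random.default_rng(7)
        coords = rng.normal(0, 5, size=(30, 3))
        base = geo.radius_of_gyration(coords)
        assert geo.radius_of_gyration(coords * scale) == pytest.approx(
            base * scale, rel=1e-9
        )


class TestGGAsymmetry:
    def _series(self, angles_by_monomer):
        import pandas as pd

        rows = [
            ("g_bse", mid, "WT", f, v)
            for mid, values in angles_by_monomer.items()
            for f, v in enumerate(values)
        ]
        return geo.AngleSeries(
            "g_bse",
            pd.DataFrame(
                rows, columns=["angle_name", "monomer_id", "genotype", "frame_index", "degrees"]
            ),
        )

    def _topology(self, pairs):
        ids = sorted({m for p in pairs for m in p})
        return AssemblyTopology(
            rung_of={m: i % 2 for i, m in enumerate(ids)},
            tetramer_of={m: 0 for m in ids},
            within_rung_neighbors={m: [] for m in ids},
            gg_partners=list(pairs),
            chain_order=ids,
        )

    def test_identical_partners_give_zero(self):
        series = self._series({"a": [120.0, 120.0], "b": [120.0, 120.0]})
        records, summary = geo.gg_asymmetry(series, self._topology([("a", "b")]))
        assert records[0].delta_deg == 0.0
        assert summary["mean_delta_deg"] == 0.0

    def test_difference_and_summary_closed_form(self):
        series = self._series(
            {"a": [150.0], "b": [118.0], "c": [130.0], "d": [130.0]}
        )
        records, summary = geo.gg_asymmetry(
            series, self._topology([("a", "b"), ("c", "d")])
        )
        deltas = {r.pair: r.delta_deg for r in records}
        assert deltas[("a", "b")] == pytest.approx(32.0)
        assert deltas[("c", "d")] == pytest.approx(0.0)
        assert summary["n_pairs"] == 2
        assert summary["mean_delta_deg"] == pytest.approx(16.0)
        # sd of [0, 32] with ddof=1 over sqrt(2)
        assert summary["sem_delta_deg"] == pytest.approx(16.0)

    def test_symmetric_in_pair_order(self):
        series = self._series({"a": [150.0], "b": [118.0]})
        _, fwd = geo.gg_asymmetry(series, self._topology([("a", "b")]))
        _, rev = geo.gg_asymmetry(series, self._topology([("b", "a")]))
        assert fwd["mean_delta_deg"] == rev["mean_delta_deg"]

    def test_missing_monomer_raises_key_error(self):
        series = self._series({"a": [150.0]})
        with pytest.raises(KeyError):
            geo.gg_asymmetry(series, self._topology([("a", "zz")]))
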