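import numpy as np
import pytest

from dynhelix import geometry as geo
from dynhelix import synthetic as syn
from dynhelix.errors import SpecError
from dynhelix.structures import OligomerFrame


def _frame(mono):
    return OligomerFrame(0, [mono], resolution="coarse_grained")


class TestBuildMonomer:
    @pytest.mark.parametrize("target", [118.0, 150.0, 147.0, 90.0, 35.0])
    def test_g_bse_target_realized_exactly(self, target):
        mono = syn.build_monomer(syn.SyntheticMonomerSpec(target_g_bse_deg=target))
        assert geo.g_bse_angle(_frame(mono), "A") == pytest.approx(target, abs=1e-6)

    @pytest.mark.parametrize("target", [109.0, 107.0, 120.0])
    def test_bse_stalk_target_realized_exactly(self, target):
        mono = syn.build_monomer(syn.SyntheticMonomerSpec(target_bse_stalk_deg=target))
        assert geo.bse_stalk_angle(_frame(mono), "A") == pytest.approx(target, abs=1e-6)

    def test_genotype_sets_residue_465_identity(self):
        wt = syn.build_monomer(syn.SyntheticMonomerSpec(genotype="WT"))
        mu = syn.build_monomer(syn.SyntheticMonomerSpec(genotype="R465W"))
        assert wt.residue_name_of(465) == "ARG"
        assert mu.residue_name_of(465) == "TRP"

    def test_degenerate_targets_rejected(self):
        with pytest.raises(SpecError):
            syn.SyntheticMonomerSpec(target_g_bse_deg=0.0)
        with pytest.raises(SpecError):
            syn.SyntheticMonomerSpec(target_g_bse_deg=180.0)


class TestBuildHelix:
    def test_default_spec_counts(self, wt_helix):
        traj, truth = wt_helix
        assert len(traj.monomer_ids) == 56
        assert len(truth["gg_pairs"]) == 41
        assert truth["n_rungs"] == 4

    def test_alternating_pattern_strictly_intercalates(self):
        traj, truth = syn.build_helix(
            syn.SyntheticHelixSpec(genotype_pattern=syn.ALTERNATING)
        )
        genos = [truth["genotype_of"][m] for m in traj.monomer_ids]
        assert genos.count("WT") == 28 and genos.count("R465W") == 28
        assert all(a != b for a, b in zip(genos, genos[1:]))
        # every cross-rung G-G pair joins opposite genotypes
        for a, b in truth["gg_pairs"]:
            assert truth["genotype_of"][a] != truth["genotype_of"][b]

    def test_fixed_seed_is_deterministic(self):
        spec = syn.SyntheticHelixSpec(n_frames=3, noise_sigma_A=0.7, seed=42)
        t1, _ = syn.build_helix(spec)
        t2, _ = syn.build_helix(spec)
        for f1, f2 in zip(t1.frames, t2.frames):
            for m1, m2 in zip(f1.monomers, f2.monomers):
                assert np.array_equal(m1.coords, m2.coords)

    def test_angle_targets_recovered_from_helix(self, wt_helix):
        traj, truth = wt_helix
        frame = traj.frames[0]
        for mid in ("M00", "M27", "M55"):
            got = geo.g_bse_angle(frame, mid)
            assert got == pytest.approx(truth["target_g_bse_deg"][mid], abs=1e-6)
            got_bs = geo.bse_stalk_angle(frame, mid)
            assert got_bs == pytest.approx(truth["target_bse_stalk_deg"][mid], abs=1e-6)

    def test_noise_ablation_converges_to_truth(self):
        """Angle estimate error shrinks as noise drops and frames accumulate."""
        errors = []
        for sigma in (2.0, 0.5, 0.0):
            traj, truth = syn.build_helix(
                syn.SyntheticHelixSpec(n_frames=8, noise_sigma_A=sigma, seed=9)
            )
            series = geo.angle_series(traj, geo.g_bse_definition())
            means = series.window_means()
            err = np.abs(
                means.set_index("monomer_id").degrees
                - pd_series(truth["target_g_bse_deg"])
            ).mean()
            errors.append(err)
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] == pytest.approx(0.0, abs=1e-9)

    def test_sem_shrinks_with_frame_count(self):
        sems = []
        for n_frames in (4, 16, 64):
            traj, _ = syn.build_helix(
                syn.SyntheticHelixSpec(n_frames=n_frames, noise_sigma_A=1.5, seed=17)
            )
            series = geo.angle_series(traj, geo.g_bse_definition())
            sub = series.data[series.data.monomer_id == "M10"].degrees
            sems.append(sub.std(ddof=1) / np.sqrt(len(sub)))
        assert sems[0] > sems[1] > sems[2]
        # roughly 1/sqrt(n): 16x frames -> ~4x smaller
        assert sems[0] / sems[2] == pytest.approx(4.0, rel=0.6)

    def test_divisibility_is_enforced(self):
        with pytest.raises(SpecError):
            syn.SyntheticHelixSpec(n_monomers=54)

    def test_nanotube_rides_along_when_requested(self):
        spec = syn.SyntheticHelixSpec(nanotube=syn.NanotubeSpec(length_A=60.0))
        traj, _ = syn.build_helix(spec)
        assert "NT" in traj.monomer_ids
        assert len(traj.monomer_ids) == 57


def pd_series(d):
    import pandas as pd

    return pd.Series(d)


class TestBuildNanotube:
    def test_default_outer_diameter(self):
        tube = syn.build_nanotube()
        radial = np.linalg.norm(tube.coords[:, :2], axis=1)
        spec = syn.NanotubeSpec()
        assert 2 * radial.max() == pytest.approx(
            spec.outer_diameter_A, abs=spec.bead_spacing_A / 2
        )

    def test_zero_length_gives_single_ring(self):
        tube = syn.build_nanotube(syn.NanotubeSpec(length_A=0.0))
        assert np.unique(tube.coords[:, 2]).size == 1

    def test_doubling_spacing_quarters_bead_count(self):
        n1 = syn.build_nanotube(syn.NanotubeSpec(length_A=120.0, bead_spacing_A=4.0)).n_atoms
        n2 = syn.build_nanotube(syn.NanotubeSpec(length_A=120.0, bead_spacing_A=8.0)).n_atoms
        assert n1 / n2 == pytest.approx(4.0, rel=0.15)

    def test_bad_spacing_rejected(self):
        with pytest.raises(SpecError):
            syn.NanotubeSpec(outer_diameter_A=10.0, bead_spacing_A=8.0)


class TestBuildDimer:
    def test_heterodimer_carries_both_genotypes(self):
        frame = syn.build_dimer("WT", "R465W")
        assert frame.monomer("A").residue_name_of(465) == "ARG"
        assert frame.monomer("B").residue_name_of(465) == "TRP"
        assert frame.resolution == "full_atom"

    def test_identical_specs_give_identical_frames(self):
        f1 = syn.build_dimer("WT", "WT", "tight")
        f2 = syn.build_dimer("WT", "WT", "tight")
        for m1, m2 in zip(f1.monomers, f2.monomers):
            assert np.array_equal(m1.coords, m2.coords)

    def test_auto_mode_follows_genotypes(self):
        from dynhelix.interfaces import count_hbonds

        tight = syn.build_dimer("WT", "WT")
        loose = syn.build_dimer("R465W", "R465W")
        assert count_hbonds(tight, ("A", "B")) > 0
        assert count_hbonds(loose, ("A", "B")) == 0

    def test_dimer_trajectory_noise_and_determinism(self):
        t1 = syn.build_dimer_trajectory("WT", "WT", n_frames=3, noise_sigma_A=0.3, seed=8)
        t2 = syn.build_dimer_trajectory("WT", "WT", n_frames=3, noise_sigma_A=0.3, seed=8)
        assert len(t1) == 3
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.monomers[0].coords, f2.monomers[0].coords)
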