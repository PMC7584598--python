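"""Seedable generator of pseudo-dynamin fixtures: dimers, helices, nanotubes.

The generator builds *reduced scaffolds*, not protein models: each monomer
carries only the ~135 residues the analyses touch (angle anchor ranges,
interface segments, the mutation site and its pocket, G-domain contact
patches), placed so that every ground-truth label is recoverable by the
corresponding analysis operation:

* the G-BSE and BSE-stalk anchor centroids realize the target angles exactly
  (wild-type-like ~118 deg, mutant-like ~150 deg G-BSE by default);
* 56 monomers wind around a cylinder (radius 180 A, rise 4 A/monomer,
  14 monomers/turn by default — a four-rung helix of 14 tetramers);
* neighboring stalk ends meet within the 6 A contact cutoff and carry the
  interface-2 marker residues (Q474, L478, E482, N487, N489 against T678 and
  its neighbors); mutant monomers retract these segments slightly, loosening
  interface-2 as the mutation does;
* residue 465 of each monomer reaches the BSE tip of its path neighbor:
  buried wild-type R465 touches P294/V744/S745, the exposed mutant W465
  additionally reaches S298/S742;
* G-domain contact patches above and below each monomer meet the patches of
  the adjacent rungs, so cross-rung G-G pairs connect monomers 15 apart along
  the path — in the alternating-genotype helix these pairs always join a
  wild-type to a mutant monomer.

Per-frame coordinate noise is isotropic Gaussian, i.i.d. per particle; the
generator is fully deterministic given (spec, seed).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import SpecError
from .structures import (
    COARSE_GRAINED,
    FULL_ATOM,
    R465W,
    WT,
    MonomerModel,
    OligomerFrame,
    Trajectory,
)

BURIED = "buried"
EXPOSED = "exposed"

WT_G_BSE_DEG = 118.0
MUTANT_G_BSE_DEG = 150.0
DEFAULT_BSE_STALK_DEG = 109.0

#: residue names for the scaffold positions that analyses look up by name
RESIDUE_NAMES = {
    294: "PRO", 298: "SER", 330: "GLN", 429: "ASN", 433: "GLN",
    463: "VAL", 464: "GLY", 465: "ARG", 466: "GLU", 467: "MET", 468: "GLU",
    474: "GLN", 478: "LEU", 482: "GLU", 484: "LYS", 487: "ASN", 489: "ASN",
    676: "GLY", 678: "THR", 681: "GLU", 692: "GLU",
    742: "SER", 744: "VAL", 745: "SER",
}


def _resname(res: int, genotype: str) -> str:
    if res == 465:
        return "TRP" if genotype == R465W else "ARG"
    return RESIDUE_NAMES.get(res, "ALA")


@dataclass(frozen=True)
class SyntheticMonomerSpec:
    target_g_bse_deg: float = WT_G_BSE_DEG
    target_bse_stalk_deg: float = DEFAULT_BSE_STALK_DEG
    genotype: str = WT
    residue465_exposure: str | None = None  # None -> buried for WT, exposed for mutant
    scaffold_scale: float = 42.0  # stalk half-length, Angstrom

    def __post_init__(self):
        for t in (self.target_g_bse_deg, self.target_bse_stalk_deg):
            if not 0.0 < t < 180.0:
                raise SpecError(f"infeasible target angle {t}: must be in (0, 180) exclusive")
        if self.scaffold_scale <= 0:
            raise SpecError("scaffold_scale must be positive")
        if self.residue465_exposure not in (None, BURIED, EXPOSED):
            raise SpecError(f"unknown exposure {self.residue465_exposure!r}")

    @property
    def exposure(self) -> str:
        if self.residue465_exposure is not None:
            return self.residue465_exposure
        return EXPOSED if self.genotype == R465W else BURIED


@dataclass(frozen=True)
class NanotubeSpec:
    outer_diameter_A: float = 137.0
    length_A: float = 200.0
    bead_spacing_A: float = 6.0

    def __post_init__(self):
        if self.outer_diameter_A <= 0:
            raise SpecError("outer_diameter_A must be positive")
        if self.bead_spacing_A <= 0 or self.bead_spacing_A > self.outer_diameter_A / 2:
            raise SpecError("bead_spacing_A must be positive and below the outer radius")
        if self.length_A < 0:
            raise SpecError("length_A must be non-negative")


ALL_WT = "all_wt"
ALTERNATING = "alternating"
ALL_MUTANT = "all_mutant"


@dataclass(frozen=True)
class SyntheticHelixSpec:
    n_monomers: int = 56
    radius_A: float = 180.0
    rise_per_monomer_A: float = 4.0
    monomers_per_turn: float = 14.0
    genotype_pattern: str = ALL_WT
    n_frames: int = 1
    noise_sigma_A: float = 0.0
    seed: int = 0
    frame_dt_ns: float = 10.0
    wt_g_bse_deg: float = WT_G_BSE_DEG
    mutant_g_bse_deg: float = MUTANT_G_BSE_DEG
    bse_stalk_deg: float = DEFAULT_BSE_STALK_DEG
    nanotube: NanotubeSpec | None = None

    def __post_init__(self):
        if self.n_monomers % 4 != 0:
            raise SpecError(f"n_monomers {self.n_monomers} not divisible by tetramer size 4")
        if self.genotype_pattern not in (ALL_WT, ALTERNATING, ALL_MUTANT):
            raise SpecError(f"unknown genotype pattern {self.genotype_pattern!r}")
        if self.genotype_pattern == ALTERNATING and self.n_monomers % 2:
            raise SpecError("alternating pattern requires an even monomer count")
        if self.noise_sigma_A < 0 or self.n_frames < 1:
            raise SpecError("noise_sigma_A must be >= 0 and n_frames >= 1")
        if self.radius_A <= 0 or self.rise_per_monomer_A < 0 or self.monomers_per_turn <= 2:
            raise SpecError("invalid helix geometry parameters")

    def genotypes(self) -> list[str]:
        if self.genotype_pattern == ALL_WT:
            return [WT] * self.n_monomers
        if self.genotype_pattern == ALL_MUTANT:
            return [R465W] * self.n_monomers
        return [WT if i % 2 == 0 else R465W for i in range(self.n_monomers)]


# ---------------------------------------------------------------------------
# coarse-grained monomer scaffold
# ---------------------------------------------------------------------------

def _rotate_nz(angle_rad: float) -> np.ndarray:
    """Unit vector in the local (radial, axial) plane at the given angle."""
    return np.array([0.0, np.cos(angle_rad), np.sin(angle_rad)])


def _cg_positions(spec: SyntheticMonomerSpec, helix: SyntheticHelixSpec) -> dict[int, np.ndarray]:
    """Local (tangent, radial-out, axial) bead positions, one per residue."""
    ts = spec.scaffold_scale / 42.0
    pos: dict[int, np.ndarray] = {}

    def put(res, t, n, z, scale_t=True):
        pos[res] = np.array([t * ts if scale_t else t, n, z])

    # stalk four-helix bundle (two marker helices along the path tangent)
    for r, t in zip(range(410, 423), np.linspace(-12, 12, 13)):
        put(r, t, 0.0, 0.0)
    for r, t in zip(range(610, 627), np.linspace(-16, 16, 17)):
        put(r, t, 1.5, -1.5)

    # interface-2 marker clusters at the stalk ends; the mutation displaces
    # them radially, pulling the alpha-S segments out of the contact zone
    mutant = spec.genotype == R465W
    plus_n = 5.5 if mutant else 0.0
    minus_n = -4.5 if mutant else 0.0
    for r, (dt, dz) in zip(
        (474, 478, 482, 487, 489),
        ((0.0, 0.4), (0.6, 0.4), (-0.6, 0.4), (0.3, -0.4), (-0.3, -0.4)),
    ):
        put(r, 40.0 + dt, plus_n, -2.5 + dz)
    for i, r in enumerate(range(674, 683)):
        put(r, -40.6 + 1.2 * i / 8.0, minus_n, -2.5 + (0.4 if i % 2 else -0.4))

    # residue 465: buried in a side-chain cage near the plus end, or exposed
    cage = np.array([38.5, 0.0, 0.0])
    for r, off in {
        429: (-2.8, 0, 0), 433: (0, 2.8, 0), 463: (0, -2.8, 0), 464: (0, 0, 2.8),
        466: (0, 0, -2.8), 467: (2.0, 2.0, 0), 468: (2.0, -2.0, 0),
    }.items():
        put(r, cage[0] + off[0], cage[1] + off[1], cage[2] + off[2])
    if spec.exposure == BURIED:
        put(465, *cage)
    else:
        put(465, 40.8, 0.5, 1.8)

    # BSE tip reaching toward the previous path neighbor's residue 465:
    # near beads within reach of a buried R465, far beads only of an exposed W465
    for r, dt in zip((294, 744, 745), (-0.3, 0.0, 0.3)):
        put(r, -39.5 + dt, 0.2, -2.0)
    for r, dt in zip((298, 742), (-0.25, 0.25)):
        put(r, -35.5 + dt, 0.8, 0.5)

    # inert markers: L1N^S loop, interface-1 anchors, a PH-domain cluster
    for i, r in enumerate(range(356, 365)):
        put(r, -23.2 + 0.8 * i, -2.5, 0.5)
    put(330, 18.0, 4.0, 0.0)
    put(692, 17.0, 5.0, 2.0)
    for i, r in enumerate(range(520, 525)):
        put(r, -4.0 + 2.0 * i, -18.0, 0.0)

    # hinge (BSE-stalk vertex): pooled centroid exactly at (0, 12, 0)
    for r, t in zip(range(315, 322), np.linspace(-1.5, 1.5, 7)):
        put(r, t, 12.0, 2.0)
    for r, t in zip(range(702, 712), np.linspace(-1.8, 1.8, 10)):
        put(r, t, 12.0, -1.4)

    # G-domain contact patches meeting the adjacent rungs (top and bottom),
    # placed on the cylinder of radius R+20 half an azimuthal step away
    delta = 2.0 * np.pi / helix.monomers_per_turn
    pitch = helix.rise_per_monomer_A * helix.monomers_per_turn
    rp = helix.radius_A + 20.0
    tp = rp * np.sin(delta / 2.0)
    npatch = rp * np.cos(delta / 2.0) - helix.radius_A
    for r, dt in zip(range(40, 45), np.linspace(-0.6, 0.6, 5)):
        put(r, tp + dt, npatch, pitch / 2.0, scale_t=False)
    for r, dt in zip(range(45, 50), np.linspace(-0.6, 0.6, 5)):
        put(r, -tp + dt, npatch, -pitch / 2.0, scale_t=False)

    # BSE-stalk angle: V4 runs from the hinge centroid to the stalk-core
    # centroid; the G-domain core is placed so that angle(V3, V4) is exact
    hinge = np.mean([pos[r] for r in range(315, 322)] + [pos[r] for r in range(702, 712)], axis=0)
    stalk_core = np.mean(
        [pos[r] for r in range(410, 423)] + [pos[r] for r in range(610, 627)], axis=0
    )
    v4 = stalk_core - hinge
    a4 = np.arctan2(v4[2], v4[1])
    theta_s = np.radians(spec.target_bse_stalk_deg)
    # choose the rotation that points the G core upward (positive axial)
    a3 = a4 + theta_s if np.sin(a4 + theta_s) >= np.sin(a4 - theta_s) else a4 - theta_s
    g_core = hinge + 20.0 * _rotate_nz(a3)
    for r, t in zip(range(30, 37), np.linspace(-1.5, 1.5, 7)):
        put(r, g_core[0] - 2.0 + t, g_core[1], g_core[2], scale_t=False)
    for r, t in zip(range(170, 177), np.linspace(-1.5, 1.5, 7)):
        put(r, g_core[0] + 2.0 + t, g_core[1], g_core[2], scale_t=False)

    # G-BSE angle: vertex above the hinge, arm centroids at the exact target
    vertex = np.array([0.0, 16.0, 2.0])
    theta_g = np.radians(spec.target_g_bse_deg)
    s_rot = 1.0 if a3 >= a4 else -1.0
    a1 = a3
    a2 = a1 - s_rot * theta_g
    arm1 = vertex + 12.0 * _rotate_nz(a1)
    arm2 = vertex + 12.0 * _rotate_nz(a2)
    for r, t in zip(range(291, 294), np.linspace(-0.8, 0.8, 3)):
        put(r, vertex[0] + t, vertex[1], vertex[2], scale_t=False)
    for r, t in zip(range(277, 286), np.linspace(-2.0, 2.0, 9)):
        put(r, arm1[0] + t, arm1[1], arm1[2], scale_t=False)
    for r, t in zip(range(299, 307), np.linspace(-1.75, 1.75, 8)):
        put(r, arm2[0] + t, arm2[1], arm2[2], scale_t=False)

    return pos


def build_monomer(
    spec: SyntheticMonomerSpec = SyntheticMonomerSpec(),
    monomer_id: str = "A",
    helix: SyntheticHelixSpec | None = None,
) -> MonomerModel:
    """A reduced coarse-grained scaffold monomer in its local frame.

    The G-BSE and BSE-stalk angles of the result equal the spec targets
    exactly (uniform-weight centroids of single-bead residues).
    """
    helix = helix or SyntheticHelixSpec()
    pos = _cg_positions(spec, helix)
    residues = sorted(pos)
    return MonomerModel(
        monomer_id,
        spec.genotype,
        atom_names=["BB"] * len(residues),
        residue_names=[_resname(r, spec.genotype) for r in residues],
        residue_numbers=residues,
        coords=np.array([pos[r] for r in residues]),
    )


# ---------------------------------------------------------------------------
# helix assembly
# ---------------------------------------------------------------------------

def _world(local: np.ndarray, radius: float, theta: float, z_center: float) -> np.ndarray:
    """Map local (tangent, radial-out, axial) coordinates onto the helix."""
    t, n, z = local[:, 0], local[:, 1], local[:, 2]
    c, s = np.cos(theta), np.sin(theta)
    return np.column_stack(
        ((radius + n) * c - t * s, (radius + n) * s + t * c, z_center + z)
    )


def build_helix(spec: SyntheticHelixSpec = SyntheticHelixSpec()) -> tuple[Trajectory, dict]:
    """A multi-frame helical assembly plus its ground-truth record.

    Monomer i sits at azimuth ``i * 2pi / monomers_per_turn`` and axial
    position ``i * rise``; the canonical scaffold centroid is subtracted so
    every monomer's center of mass lies exactly on the cylinder of the
    requested radius.  Ground truth carries the true helix parameters,
    genotype map, rung and tetramer labels, target angles and contact pairs.
    """
    genos = spec.genotypes()
    delta = 2.0 * np.pi / spec.monomers_per_turn
    pitch = spec.rise_per_monomer_A * spec.monomers_per_turn

    canonical = _cg_positions(
        SyntheticMonomerSpec(
            target_g_bse_deg=spec.wt_g_bse_deg,
            target_bse_stalk_deg=spec.bse_stalk_deg,
            genotype=WT,
        ),
        spec,
    )
    mu = np.mean(list(canonical.values()), axis=0)

    ids = [f"M{i:02d}" for i in range(spec.n_monomers)]
    templates = []
    for i, geno in enumerate(genos):
        mono_spec = SyntheticMonomerSpec(
            target_g_bse_deg=spec.mutant_g_bse_deg if geno == R465W else spec.wt_g_bse_deg,
            target_bse_stalk_deg=spec.bse_stalk_deg,
            genotype=geno,
        )
        pos = _cg_positions(mono_spec, spec)
        residues = sorted(pos)
        local = np.array([pos[r] for r in residues]) - mu
        world = _world(local, spec.radius_A, i * delta, i * spec.rise_per_monomer_A)
        templates.append((residues, world, geno))

    nanotube_monomer = build_nanotube(spec.nanotube) if spec.nanotube else None

    rng = np.random.default_rng(spec.seed)
    frames = []
    for f in range(spec.n_frames):
        monomers = []
        for mid, (residues, world, geno) in zip(ids, templates):
            coords = world
            if spec.noise_sigma_A > 0:
                coords = world + rng.normal(0.0, spec.noise_sigma_A, size=world.shape)
            monomers.append(
                MonomerModel(
                    mid,
                    geno,
                    atom_names=["BB"] * len(residues),
                    residue_names=[_resname(r, geno) for r in residues],
                    residue_numbers=residues,
                    coords=coords,
                )
            )
        if nanotube_monomer is not None:
            coords = nanotube_monomer.coords
            if spec.noise_sigma_A > 0:
                coords = coords + rng.normal(0.0, spec.noise_sigma_A, size=coords.shape)
            monomers.append(nanotube_monomer.with_coords(coords))
        frames.append(
            OligomerFrame(
                frame_index=f,
                time_ns=f * spec.frame_dt_ns,
                monomers=monomers,
                resolution=COARSE_GRAINED,
            )
        )

    n_rungs = int(np.ceil(spec.n_monomers / spec.monomers_per_turn))
    truth = {
        "radius_A": spec.radius_A,
        "diameter_A": 2.0 * spec.radius_A,
        "rise_per_monomer_A": spec.rise_per_monomer_A,
        "monomers_per_turn": spec.monomers_per_turn,
        "pitch_A": pitch,
        "helix_angle_deg": float(
            np.degrees(np.arctan2(spec.rise_per_monomer_A, spec.radius_A * delta))
        ),
        "n_rungs": n_rungs,
        "genotype_of": dict(zip(ids, genos)),
        "rung_of": {mid: int(i // spec.monomers_per_turn) for i, mid in enumerate(ids)},
        "tetramer_of": {mid: i // 4 for i, mid in enumerate(ids)},
        "target_g_bse_deg": {
            mid: (spec.mutant_g_bse_deg if g == R465W else spec.wt_g_bse_deg)
            for mid, g in zip(ids, genos)
        },
        "target_bse_stalk_deg": {mid: spec.bse_stalk_deg for mid in ids},
        "path_pairs": [[ids[i], ids[i + 1]] for i in range(spec.n_monomers - 1)],
        "gg_pairs": [
            [ids[i], ids[i + 15]] for i in range(spec.n_monomers - 15)
        ],
        "seed": spec.seed,
    }
    traj = Trajectory(frames=frames, metadata={"generator": "build_helix", "spec_seed": spec.seed})
    return traj, truth


def write_ground_truth(truth: dict, path) -> None:
    """Sidecar JSON next to a written structure file."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# lipid-head nanotube
# ---------------------------------------------------------------------------

def build_nanotube(spec: NanotubeSpec = NanotubeSpec(), monomer_id: str = "NT") -> MonomerModel:
    """Cylindrical lattice of lipid-head beads (one pseudo-molecule).

    Bead centers lie exactly on the outer radius; rings are spaced
    ``bead_spacing_A`` apart along the axis (a zero length gives one ring).
    """
    r = spec.outer_diameter_A / 2.0
    n_rings = int(np.floor(spec.length_A / spec.bead_spacing_A)) + 1
    n_per_ring = max(3, int(round(2.0 * np.pi * r / spec.bead_spacing_A)))
    coords = []
    for k in range(n_rings):
        z = k * spec.bead_spacing_A - (n_rings - 1) * spec.bead_spacing_A / 2.0
        ang = 2.0 * np.pi * (np.arange(n_per_ring) + 0.5 * (k % 2)) / n_per_ring
        ring = np.column_stack((r * np.cos(ang), r * np.sin(ang), np.full(n_per_ring, z)))
        coords.append(ring)
    coords = np.concatenate(coords)
    n = len(coords)
    return MonomerModel(
        monomer_id,
        WT,
        atom_names=["NT"] * n,
        residue_names=["LIP"] * n,
        residue_numbers=np.arange(1, n + 1),
        coords=coords,
    )


# ---------------------------------------------------------------------------
# full-atom dimer
# ---------------------------------------------------------------------------

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

TIGHT = "tight"
LOOSENED = "loosened"
AUTO = "auto"

#: extra y-offset applied to the second monomer in loosened mode (Angstrom)
LOOSEN_OFFSET = 2.5


def _fa_template(genotype: str) -> list[tuple[int, str, str, np.ndarray]]:
    """Full-atom template of one dimer monomer in its local frame.

    The interface plane is y = 0; functional donor/acceptor atoms sit at
    y ~ -1.45 so that the C2-related partner places its counterpart at +1.45
    (hydrogen-bond distance 2.9 A, salt-bridge distance 3.5 A).
    """
    atoms: list[tuple[int, str, str, np.ndarray]] = []

    def put(res, name, x, y, z):
        atoms.append((res, _resname(res, genotype), name, np.array([x, y, z], float)))

    def backbone(res, cx, cy, cz, skip_o=False):
        put(res, "N", cx - 0.6, cy - 0.3, cz - 0.4)
        put(res, "CA", cx, cy, cz)
        put(res, "C", cx + 0.6, cy - 0.3, cz - 0.4)
        if not skip_o:
            put(res, "O", cx + 0.9, cy - 1.1, cz - 0.6)

    # stalk scaffolding rows, well below the interface and away from 465
    for r, x in zip(range(410, 423), np.linspace(-24, 24, 13)):
        backbone(r, x, -16.0, 0.0)
    for r, x in zip(range(610, 627), np.linspace(-28, 28, 17)):
        backbone(r, x, -19.0, 0.0)

    # interface-2 plus end (alpha-S2/S3 side)
    backbone(474, 20.0, -3.0, 0.0)
    put(474, "CD", 20.0, -2.8, 0.0)
    put(474, "NE2", 20.0, -1.45, 0.0)
    put(474, "OE1", 21.0, -2.6, 0.8)
    backbone(478, 23.0, -4.0, -1.0)
    put(478, "CD1", 23.5, -3.3, -0.5)
    backbone(482, 26.0, -3.5, 1.0)
    put(482, "OE1", 26.0, -2.6, 1.2)
    put(482, "OE2", 26.8, -3.4, 1.8)
    put(482, "CD", 26.3, -3.4, 1.1)
    backbone(484, 22.0, -4.0, -2.0)
    put(484, "CE", 22.0, -3.0, -2.0)
    put(484, "NZ", 22.0, -1.75, -2.0)
    backbone(487, 24.0, -3.0, 0.0)
    put(487, "CG", 24.0, -2.8, 0.0)
    put(487, "ND2", 24.0, -1.45, 0.0)
    put(487, "OD1", 24.8, -2.6, -0.8)
    backbone(489, 28.0, -3.0, 1.0)
    put(489, "CG", 28.0, -2.8, 1.0)
    put(489, "ND2", 28.0, -1.45, 1.0)
    put(489, "OD1", 28.8, -2.6, 1.6)

    # interface-2 minus end (alpha-S4 side)
    backbone(674, -18.0, -4.0, 0.0)
    backbone(675, -19.0, -4.5, 1.0)
    backbone(676, -24.0, -3.0, 0.0, skip_o=True)
    put(676, "O", -24.0, -1.45, 0.0)  # backbone acceptor at the interface
    backbone(677, -22.0, -4.0, -1.0)
    backbone(678, -20.0, -3.0, 0.0)
    put(678, "CB", -20.0, -2.8, 0.0)
    put(678, "OG1", -20.0, -1.45, 0.0)
    backbone(679, -26.0, -4.0, 1.0)
    backbone(680, -28.0, -3.0, 1.0, skip_o=True)
    put(680, "O", -28.0, -1.45, 1.0)
    backbone(681, -22.0, -4.0, -2.0)
    put(681, "CD", -22.0, -3.0, -2.0)
    put(681, "OE1", -22.0, -1.75, -2.0)
    put(681, "OE2", -22.0, -2.5, -2.8)
    backbone(682, -30.0, -4.0, 0.0)

    # residue 465 and its intra-monomer partner network
    c465 = np.array([10.0, -8.0, 0.0])
    backbone(465, *(c465 + (-1.5, -1.0, -0.8)))
    if genotype == R465W:
        put(465, "CD1", 10.3, -7.7, 0.9)
        put(465, "NE1", 9.5, -7.3, 0.5)
        put(465, "CZ2", 10.9, -7.2, -0.5)
        # mutation breaks the pocket: partners pushed out of contact range
        partner_centers = {429: (2.5, -5.0, 3.0), 433: (16.0, -13.0, -3.5),
                           466: (16.0, -11.5, 3.5), 468: (2.0, -13.0, -3.0)}
        for res, (x, y, z) in partner_centers.items():
            backbone(res, x, y, z)
            if res == 429:
                put(res, "OD1", x + 0.8, y + 0.6, z)
                put(res, "ND2", x - 0.6, y + 0.8, z + 0.5)
                put(res, "CG", x, y + 0.3, z + 0.2)
            elif res == 433:
                put(res, "OE1", x + 0.6, y + 0.8, z)
                put(res, "NE2", x - 0.7, y + 0.6, z - 0.4)
                put(res, "CD", x, y + 0.3, z - 0.2)
            else:
                put(res, "OE1", x + 0.6, y + 0.9, z)
                put(res, "OE2", x - 0.6, y + 0.9, z - 0.5)
                put(res, "CD", x, y + 0.4, z - 0.2)
    else:
        put(465, "NE", 9.2, -7.6, 0.0)
        put(465, "CZ", 10.0, -7.5, 0.3)
        put(465, "NH1", 10.6, -6.9, 0.8)
        put(465, "NH2", 10.8, -7.9, -0.4)
        # guanidinium within hydrogen-bond/salt-bridge reach of the pocket
        backbone(429, 5.5, -6.5, 1.5)
        put(429, "CG", 6.6, -6.2, 1.1)
        put(429, "OD1", 7.0, -6.0, 1.0)
        put(429, "ND2", 6.0, -5.4, 0.8)
        backbone(433, 13.0, -10.8, -2.2)
        put(433, "CD", 12.6, -10.3, -1.8)
        put(433, "OE1", 12.2, -10.1, -1.6)
        put(433, "NE2", 13.4, -9.9, -2.4)
        backbone(466, 13.8, -4.6, 2.4)
        put(466, "CD", 13.0, -4.9, 2.0)
        put(466, "OE1", 12.6, -5.1, 1.8)
        put(466, "OE2", 13.4, -4.3, 1.4)
        backbone(468, 9.4, -11.4, 1.4)
        put(468, "CD", 9.6, -10.8, 1.1)
        put(468, "OE1", 9.8, -10.3, 0.8)
        put(468, "OE2", 8.9, -11.0, 1.9)
    # inert flanks, out of contact range of residue 465
    backbone(463, 1.0, -14.0, -4.5)
    backbone(464, 17.0, -12.5, 4.0)
    backbone(467, 15.5, -13.5, -4.5)
    return atoms


def _monomer_from_atoms(monomer_id, genotype, atoms, transform):
    order = sorted(range(len(atoms)), key=lambda k: atoms[k][0])
    names, rnames, rnums, coords = [], [], [], []
    for k in order:
        res, rname, aname, xyz = atoms[k]
        names.append(aname)
        rnames.append(rname)
        rnums.append(res)
        coords.append(transform(xyz))
    masses = [_ELEMENT_MASS[n[:1]] for n in names]
    return MonomerModel(
        monomer_id,
        genotype,
        atom_names=names,
        residue_names=rnames,
        residue_numbers=rnums,
        coords=np.array(coords),
        masses=masses,
    )


def build_dimer(
    genotype_a: str = WT,
    genotype_b: str = WT,
    interface_mode: str = AUTO,
) -> OligomerFrame:
    """Full-atom dimer joined crisscross through the stalk alpha-S2..S4 ends.

    ``tight`` realizes six cross-monomer hydrogen bonds and two salt bridges
    by construction; ``loosened`` pulls the second monomer away so the bonds
    break and some contact residues drop out.  ``auto`` picks tight when both
    monomers are wild type and loosened otherwise — the mutation destabilizes
    this interface.
    """
    if interface_mode not in (TIGHT, LOOSENED, AUTO):
        raise SpecError(f"unknown interface_mode {interface_mode!r}")
    if interface_mode == AUTO:
        interface_mode = TIGHT if (genotype_a == WT and genotype_b == WT) else LOOSENED
    offset = LOOSEN_OFFSET if interface_mode == LOOSENED else 0.0

    mono_a = _monomer_from_atoms("A", genotype_a, _fa_template(genotype_a), lambda p: p)
    mono_b = _monomer_from_atoms(
        "B",
        genotype_b,
        _fa_template(genotype_b),
        lambda p: np.array([-p[0], -p[1] + offset, p[2]]),
    )
    return OligomerFrame(frame_index=0, monomers=[mono_a, mono_b], resolution=FULL_ATOM)


def build_dimer_trajectory(
    genotype_a: str = WT,
    genotype_b: str = WT,
    interface_mode: str = AUTO,
    n_frames: int = 1,
    noise_sigma_A: float = 0.0,
    seed: int = 0,
    frame_dt_ns: float = 1.0,
) -> Trajectory:
    """Replicated dimer frames with i.i.d. Gaussian coordinate noise."""
    base = build_dimer(genotype_a, genotype_b, interface_mode)
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        monomers = []
        for m in base.monomers:
            coords = m.coords
            if noise_sigma_A > 0:
                coords = coords + rng.normal(0.0, noise_sigma_A, size=coords.shape)
            monomers.append(m.with_coords(coords))
        frames.append(
            OligomerFrame(
                frame_index=f, time_ns=f * frame_dt_ns, monomers=monomers, resolution=FULL_ATOM
            )
        )
    return Trajectory(frames=frames, metadata={"generator": "build_dimer_trajectory", "seed": seed})
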