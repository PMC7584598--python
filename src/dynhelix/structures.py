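"""In-memory containers for multi-monomer coordinate ensembles.

A :class:`MonomerModel` stores one protein (or pseudo-molecule) as flat numpy
arrays — one entry per particle — which keeps 56-monomer, multi-frame
ensembles cheap.  An :class:`OligomerFrame` is one time point of an assembly;
a :class:`Trajectory` is an ordered list of frames sharing the same monomers.

Residue numbering is 1-based human dynamin-2 numbering throughout; insertion
codes are not supported.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, SelectionError, WindowError

WT = "WT"
R465W = "R465W"

#: default coarse-grained bead names (4-to-1 mapping style: one backbone bead
#: plus up to four side-chain beads)
CG_BEAD_NAMES = ("BB", "SC1", "SC2", "SC3", "SC4")

RangeSet = tuple[tuple[int, int], ...]


@dataclass
class AtomRecord:
    """A single particle (atom or coarse-grained bead)."""

    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    monomer_id: str
    position: np.ndarray
    mass: float | None = None
    radius: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive when present")


class MonomerModel:
    """One monomer: parallel per-particle arrays plus identity metadata.

    Parameters
    ----------
    monomer_id:
        Chain identifier (PDB chain id / mmCIF auth_asym_id).
    genotype:
        ``"WT"`` or ``"R465W"``.  Checked against the name of residue 465
        when that residue is present (TRP for the mutant, ARG for WT).
    """

    def __init__(
        self,
        monomer_id: str,
        genotype: str = WT,
        *,
        atom_names: Sequence[str],
        residue_names: Sequence[str],
        residue_numbers: Sequence[int],
        coords: np.ndarray,
        serials: Sequence[int] | None = None,
        masses: Sequence[float] | None = None,
        radii: Sequence[float] | None = None,
    ):
        n = len(atom_names)
        self.monomer_id = str(monomer_id)
        self.genotype = genotype
        self.atom_names = list(atom_names)
        self.residue_names = list(residue_names)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.serials = (
            np.asarray(serials, dtype=int) if serials is not None else np.arange(1, n + 1)
        )
        self.masses = None if masses is None else np.asarray(masses, dtype=float)
        self.radii = None if radii is None else np.asarray(radii, dtype=float)
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_atoms(cls, monomer_id: str, atoms: Iterable[AtomRecord], genotype: str = WT):
        atoms = list(atoms)
        return cls(
            monomer_id,
            genotype,
            atom_names=[a.atom_name for a in atoms],
            residue_names=[a.residue_name for a in atoms],
            residue_numbers=[a.residue_number for a in atoms],
            coords=np.array([a.position for a in atoms], dtype=float),
            serials=[a.serial for a in atoms],
            masses=None if any(a.mass is None for a in atoms) else [a.mass for a in atoms],
            radii=None if any(a.radius is None for a in atoms) else [a.radius for a in atoms],
        )

    def _validate(self):
        n = self.n_atoms
        for name, length in (
            ("residue_names", len(self.residue_names)),
            ("residue_numbers", len(self.residue_numbers)),
            ("coords", len(self.coords)),
        ):
            if length != n:
                raise ValueError(f"{name} length {length} != {n} atoms")
        if n and self.residue_numbers.min() < 1:
            raise ValueError("residue numbers must be >= 1 (1-based dynamin-2 numbering)")
        # residue blocks must appear in strictly increasing order
        nums = self.residue_numbers
        block_starts = np.flatnonzero(np.diff(nums) != 0) + 1
        blocks = nums[np.concatenate(([0], block_starts))] if n else nums
        if len(blocks) != len(set(blocks.tolist())) or np.any(np.diff(blocks) <= 0):
            raise ValueError(f"residue numbers of monomer {self.monomer_id} not strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._check_genotype()

    _STANDARD_AA = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }

    def _check_genotype(self):
        idx = np.flatnonzero(self.residue_numbers == 465)
        if idx.size == 0:
            return
        name = self.residue_names[idx[0]]
        if name not in self._STANDARD_AA:  # non-protein pseudo-molecule
            return
        expected = "TRP" if self.genotype == R465W else "ARG"
        if name != expected:
            raise ConsistencyError(
                f"monomer {self.monomer_id}: genotype {self.genotype} but residue 465 is {name}"
            )

    # -- basic queries --------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def present_residues(self) -> np.ndarray:
        """Sorted unique residue numbers present in this monomer."""
        return np.unique(self.residue_numbers)

    def residue_name_of(self, residue_number: int) -> str:
        idx = np.flatnonzero(self.residue_numbers == residue_number)
        if idx.size == 0:
            raise SelectionError(
                f"residue {residue_number} absent from monomer {self.monomer_id}"
            )
        return self.residue_names[idx[0]]

    def select_residues(self, numbers: Iterable[int]) -> np.ndarray:
        """Indices of particles whose residue number is in ``numbers``."""
        return np.flatnonzero(np.isin(self.residue_numbers, np.fromiter(numbers, dtype=int)))

    def select_ranges(self, ranges: RangeSet, *, strict: bool = False) -> np.ndarray:
        """Indices of particles in any inclusive ``(start, stop)`` range.

        With ``strict=True`` a :class:`SelectionError` lists residue numbers
        of the ranges that resolved to nothing.
        """
        mask = np.zeros(self.n_atoms, dtype=bool)
        missing = []
        for lo, hi in ranges:
            m = (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
            if strict and not m.any():
                missing.append(f"{lo}-{hi}")
            mask |= m
        if strict and missing:
            raise SelectionError(
                f"monomer {self.monomer_id}: no atoms in residue range(s) {', '.join(missing)}"
            )
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "MonomerModel":
        """A shallow copy sharing metadata but with new coordinates."""
        out = copy.copy(self)
        out.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return out

    def __repr__(self):
        return (
            f"<MonomerModel {self.monomer_id} ({self.genotype}) "
            f"{len(self.present_residues)} residues / {self.n_atoms} particles>"
        )


FULL_ATOM = "full_atom"
COARSE_GRAINED = "coarse_grained"


@dataclass
class OligomerFrame:
    """One time point of a multi-monomer assembly."""

    frame_index: int
    monomers: list[MonomerModel]
    resolution: str = FULL_ATOM
    time_ns: float | None = None

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not self.monomers:
            raise ValueError("a frame needs at least one monomer")
        if self.time_ns is not None and self.time_ns < 0:
            raise ValueError("time_ns must be non-negative")
        if self.resolution not in (FULL_ATOM, COARSE_GRAINED):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        ids = [m.monomer_id for m in self.monomers]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate monomer ids in frame")
        self._by_id = {m.monomer_id: m for m in self.monomers}

    @property
    def monomer_ids(self) -> list[str]:
        return [m.monomer_id for m in self.monomers]

    def monomer(self, monomer_id: str) -> MonomerModel:
        try:
            return self._by_id[monomer_id]
        except KeyError:
            raise KeyError(f"monomer {monomer_id!r} not in frame {self.frame_index}") from None

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)):
        """Rigid-body transformed copy (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        monomers = [m.with_coords(m.coords @ R.T + t) for m in self.monomers]
        return replace(self, monomers=monomers)


@dataclass
class Trajectory:
    """Ordered list of frames over the same assembly."""

    frames: list[OligomerFrame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise ValueError("empty trajectory")
        ids0 = self.frames[0].monomer_ids
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ConsistencyError("frame_index must be strictly increasing")
        for f in self.frames[1:]:
            if f.monomer_ids != ids0:
                missing = set(ids0).symmetric_difference(f.monomer_ids)
                raise ConsistencyError(
                    f"monomer set differs at frame {f.frame_index}: {sorted(missing)}"
                )

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def monomer_ids(self) -> list[str]:
        return self.frames[0].monomer_ids

    @property
    def resolution(self) -> str:
        return self.frames[0].resolution


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------

def _ranges(*pairs) -> RangeSet:
    return tuple((int(a), int(b)) for a, b in pairs)


@dataclass(frozen=True)
class DomainMap:
    """Named residue ranges of dynamin-2 used by all analyses.

    The four domain ranges (g_domain / bse / stalk / ph) drive interface
    classification; the anchor ranges define the two inter-domain angles:

    * G-BSE angle: vertex at the centroid of residues 291-293, arms to the
      centroids of 277-285 and 299-306.
    * BSE-stalk angle: vertex at the pooled centroid of the hinge
      (315-321 and 702-711), arms to the pooled centroids of the G-domain
      core (30-36, 170-176) and the stalk core (410-422, 610-626).

    All ranges are inclusive and overridable via config.
    """

    g_domain: RangeSet = _ranges((30, 293))
    bse: RangeSet = _ranges((1, 29), (294, 321), (698, 746))
    stalk: RangeSet = _ranges((322, 499), (643, 697))
    ph: RangeSet = _ranges((500, 642))
    g_bse_vertex: RangeSet = _ranges((291, 293))
    g_bse_arm1: RangeSet = _ranges((277, 285))
    g_bse_arm2: RangeSet = _ranges((299, 306))
    hinge: RangeSet = _ranges((315, 321), (702, 711))
    g_center: RangeSet = _ranges((30, 36), (170, 176))
    stalk_center: RangeSet = _ranges((410, 422), (610, 626))
    mutation_site: int = 465
    interface1_anchors: tuple[int, ...] = (330, 692)
    #: central alpha-S2..S4 stalk segments that mark interface-2
    if2_segments: RangeSet = _ranges((455, 495), (660, 690))
    #: L1N^S stalk loop marking interface-3 (approximate; not printed anywhere)
    l1ns: RangeSet = _ranges((356, 364))

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("mutation_site", "interface1_anchors"):
                continue
            for lo, hi in v:
                if lo < 0 or hi < lo:
                    raise ValueError(f"invalid range {lo}-{hi} in {f.name}")

    def domain_of(self, residue_number: int) -> str | None:
        """Which of the four domains a residue belongs to (None if unmapped)."""
        for name in ("g_domain", "bse", "stalk", "ph"):
            for lo, hi in getattr(self, name):
                if lo <= residue_number <= hi:
                    return name
        return None

    @classmethod
    def from_dict(cls, overrides: Mapping) -> "DomainMap":
        """Build from a (YAML-derived) mapping; lists of [start, stop] pairs."""
        kw = {}
        for f in fields(cls):
            if f.name not in overrides:
                continue
            v = overrides[f.name]
            if f.name == "mutation_site":
                kw[f.name] = int(v)
            elif f.name == "interface1_anchors":
                kw[f.name] = tuple(int(x) for x in v)
            else:
                kw[f.name] = _ranges(*v)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Analysis windows
# ---------------------------------------------------------------------------

LAST_N_FRAMES = "last_n_frames"
LAST_T_NS = "last_t_ns"
ALL = "all"


@dataclass(frozen=True)
class WindowSpec:
    """Which suffix of a trajectory an analysis averages over.

    The source study averages dimer metrics over the last 10 ns and helix
    metrics over the last 500 ns of simulation; the saving interval being
    unknown, a frame-count mode is provided as fallback.
    """

    mode: str = ALL
    value: float = 0.0

    def __post_init__(self):
        if self.mode not in (LAST_N_FRAMES, LAST_T_NS, ALL):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.mode != ALL and self.value <= 0:
            raise ValueError("window value must be positive")


def select_window(trajectory: Trajectory, spec: WindowSpec) -> Trajectory:
    """Suffix of ``trajectory`` satisfying ``spec`` (idempotent)."""
    frames = trajectory.frames
    if spec.mode == ALL:
        kept = frames
    elif spec.mode == LAST_N_FRAMES:
        n = int(spec.value)
        if n > len(frames):
            raise WindowError(f"window of {n} frames > trajectory length {len(frames)}")
        kept = frames[-n:]
    else:  # LAST_T_NS
        if any(f.time_ns is None for f in frames):
            raise WindowError("last_t_ns window requested but frames lack time_ns stamps")
        t_end = frames[-1].time_ns
        kept = [f for f in frames if f.time_ns >= t_end - spec.value]
    if not kept:
        raise WindowError("analysis window selected no frames")
    meta = dict(trajectory.metadata)
    meta["window"] = {"mode": spec.mode, "value": spec.value}
    return Trajectory(frames=list(kept), metadata=meta)
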