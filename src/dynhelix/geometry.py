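"""Centroid-based vector geometry: inter-domain angles, Rg, G-G asymmetry.

The two angles that report BSE conformation are defined from residue-range
centroids of a single monomer:

* **G-BSE angle** — vertex at the center of mass of residues 291-293, arms to
  the centers of mass of residues 277-285 (V1, into the G domain) and 299-306
  (V2, into the BSE).  A wild-type-like bent BSE sits near 118 degrees; the
  R465W mutant favors an extended conformation near 150 degrees.
* **BSE-stalk angle** — vertex at the pooled center of mass of the hinge
  (residues 315-321 and 702-711); V3 runs to the pooled center of the
  G-domain core (30-36, 170-176) and V4 to the stalk core (410-422, 610-626).

Center of mass is mass-weighted for full-atom monomers and uniform for
coarse-grained beads (whose masses are scheme-dependent and often absent).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, SelectionError
from .structures import (
    COARSE_GRAINED,
    DomainMap,
    MonomerModel,
    OligomerFrame,
    Trajectory,
    WindowSpec,
    select_window,
)
from .topology import AssemblyTopology

MASS = "mass"
UNIFORM = "uniform"
AUTO = "auto"


@dataclass(frozen=True)
class AngleDefinition:
    """A named inter-domain angle given by three residue-range sets."""

    name: str
    vertex_ranges: tuple
    arm1_ranges: tuple
    arm2_ranges: tuple

    def __post_init__(self):
        for rs in (self.vertex_ranges, self.arm1_ranges, self.arm2_ranges):
            if not rs:
                raise ValueError(f"{self.name}: empty range set")


def g_bse_definition(dmap: DomainMap | None = None) -> AngleDefinition:
    d = dmap or DomainMap()
    return AngleDefinition("g_bse", d.g_bse_vertex, d.g_bse_arm1, d.g_bse_arm2)


def bse_stalk_definition(dmap: DomainMap | None = None) -> AngleDefinition:
    d = dmap or DomainMap()
    return AngleDefinition("bse_stalk", d.hinge, d.g_center, d.stalk_center)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def center_of_mass(coords: np.ndarray, masses=None, weighting: str = MASS) -> np.ndarray:
    """Weighted mean position; ``weighting='uniform'`` ignores masses."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise SelectionError("center_of_mass of an empty atom list")
    coords = coords.reshape(-1, 3)
    if weighting == UNIFORM or masses is None:
        if weighting == MASS and masses is None:
            raise SelectionError("mass weighting requested but masses are absent")
        return coords.mean(axis=0)
    w = np.asarray(masses, dtype=float)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def angle_between(v1, v2) -> float:
    """Angle between two vectors in degrees, clamped into [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateGeometryError("angle_between requires nonzero vectors")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def radius_of_gyration(coords, masses=None, weighting: str = UNIFORM) -> float:
    """sqrt of the weighted mean squared distance to the center of mass (Angstrom)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.size == 0:
        raise SelectionError("radius_of_gyration of an empty atom list")
    com = center_of_mass(coords, masses, weighting)
    d2 = ((coords - com) ** 2).sum(axis=1)
    if weighting == UNIFORM or masses is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(masses, dtype=float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _resolve_weighting(monomer: MonomerModel, weighting: str, resolution: str) -> str:
    if weighting != AUTO:
        return weighting
    if resolution == COARSE_GRAINED or monomer.masses is None:
        return UNIFORM
    return MASS


def _range_com(monomer: MonomerModel, ranges, weighting: str) -> np.ndarray:
    idx = monomer.select_ranges(ranges, strict=True)
    masses = None if monomer.masses is None else monomer.masses[idx]
    return center_of_mass(monomer.coords[idx], masses, weighting)


def monomer_angle(
    monomer: MonomerModel,
    definition: AngleDefinition,
    weighting: str = UNIFORM,
) -> float:
    """Angle (degrees) defined by three residue-range centroids of one monomer."""
    vertex = _range_com(monomer, definition.vertex_ranges, weighting)
    a1 = _range_com(monomer, definition.arm1_ranges, weighting)
    a2 = _range_com(monomer, definition.arm2_ranges, weighting)
    return angle_between(a1 - vertex, a2 - vertex)


def g_bse_angle(
    frame: OligomerFrame,
    monomer_id: str,
    dmap: DomainMap | None = None,
    weighting: str = AUTO,
) -> float:
    """G-BSE angle (degrees) of one monomer in one frame."""
    mono = frame.monomer(monomer_id)
    w = _resolve_weighting(mono, weighting, frame.resolution)
    return monomer_angle(mono, g_bse_definition(dmap), w)


def bse_stalk_angle(
    frame: OligomerFrame,
    monomer_id: str,
    dmap: DomainMap | None = None,
    weighting: str = AUTO,
) -> float:
    """BSE-stalk angle (degrees) of one monomer in one frame."""
    mono = frame.monomer(monomer_id)
    w = _resolve_weighting(mono, weighting, frame.resolution)
    return monomer_angle(mono, bse_stalk_definition(dmap), w)


# ---------------------------------------------------------------------------
# series over trajectories
# ---------------------------------------------------------------------------

@dataclass
class AngleSeries:
    """Per-monomer, per-frame angles (degrees) with genotype labels.

    ``data`` columns: angle_name, monomer_id, genotype, frame_index, degrees.
    """

    angle_name: str
    data: pd.DataFrame

    def window_means(self) -> pd.DataFrame:
        """Per-monomer mean over the frames present (the statistical unit)."""
        g = (
            self.data.groupby(["monomer_id", "genotype"], sort=True)["degrees"]
            .mean()
            .reset_index()
        )
        g.insert(0, "angle_name", self.angle_name)
        return g

    def mean_of(self, monomer_id: str) -> float:
        sub = self.data[self.data.monomer_id == monomer_id]
        if sub.empty:
            raise KeyError(f"monomer {monomer_id!r} absent from angle series")
        return float(sub.degrees.mean())


def angle_series(
    trajectory: Trajectory,
    definition: AngleDefinition,
    weighting: str = AUTO,
    window: WindowSpec | None = None,
) -> AngleSeries:
    """Compute an angle for every monomer of every (windowed) frame."""
    traj = select_window(trajectory, window) if window is not None else trajectory
    # selections are identical across frames; resolve once on the first frame
    sel = {}
    for mono in traj.frames[0].monomers:
        w = _resolve_weighting(mono, weighting, traj.resolution)
        entries = []
        for ranges in (definition.vertex_ranges, definition.arm1_ranges, definition.arm2_ranges):
            idx = mono.select_ranges(ranges, strict=True)
            m = None if (mono.masses is None or w == UNIFORM) else mono.masses[idx]
            entries.append((idx, m))
        sel[mono.monomer_id] = entries

    rows = []
    for frame in traj.frames:
        for mono in frame.monomers:
            (vi, vm), (ai, am), (bi, bm) = sel[mono.monomer_id]
            vx = center_of_mass(mono.coords[vi], vm, UNIFORM if vm is None else MASS)
            a1 = center_of_mass(mono.coords[ai], am, UNIFORM if am is None else MASS)
            a2 = center_of_mass(mono.coords[bi], bm, UNIFORM if bm is None else MASS)
            rows.append(
                (
                    definition.name,
                    mono.monomer_id,
                    mono.genotype,
                    frame.frame_index,
                    angle_between(a1 - vx, a2 - vx),
                )
            )
    df = pd.DataFrame(
        rows, columns=["angle_name", "monomer_id", "genotype", "frame_index", "degrees"]
    )
    return AngleSeries(angle_name=definition.name, data=df)


# ---------------------------------------------------------------------------
# G-G bending asymmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsymmetryRecord:
    """|difference| of window-mean G-BSE angles across one G-G pair."""

    pair: tuple[str, str]
    delta_deg: float
    window_averaged: bool = True


def gg_asymmetry(
    angles: AngleSeries,
    topology: AssemblyTopology,
) -> tuple[list[AsymmetryRecord], dict]:
    """Per G-G pair Delta = |mean angle(a) - mean angle(b)| plus a summary.

    Angles are averaged per monomer over the frames present in ``angles``
    (apply a window with :func:`angle_series` first), then differenced per
    cross-rung G-G pair.  Summary reports mean +/- SEM over pairs.
    """
    records = []
    for a, b in topology.gg_partners:
        delta = abs(angles.mean_of(a) - angles.mean_of(b))
        records.append(AsymmetryRecord(pair=(a, b), delta_deg=delta))
    deltas = np.array([r.delta_deg for r in records])
    n = len(deltas)
    summary = {
        "n_pairs": n,
        "mean_delta_deg": float(deltas.mean()) if n else float("nan"),
        "sem_delta_deg": float(deltas.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    }
    return records, summary
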