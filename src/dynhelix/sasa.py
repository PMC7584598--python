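"""Solvent-accessible surface area by Shrake-Rupley sphere-point quadrature.

Each particle is inflated by the probe radius (water, 1.4 Angstrom) and
covered with a deterministic generalized-spiral point set; its SASA is the
inflated-sphere area times the fraction of points not buried inside any
neighbor's inflated sphere.  Per-residue SASA is normalized by an empirical
maximal (Gly-X-Gly) per-residue SASA table, giving a dimensionless relative
exposure.

Coarse-grained beads default to a 2.3 Angstrom radius (typical of 4-to-1
mappings); full-atom radii fall back to element values.  Both tables are
packaged CSV files and user-overridable.
"""
from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import RadiiTableError, SelectionError, WindowError
from .structures import (
    DomainMap,
    MonomerModel,
    OligomerFrame,
    Trajectory,
    WindowSpec,
    select_window,
)

log = logging.getLogger(__name__)

ISOLATED_MONOMER = "isolated_monomer"
IN_ASSEMBLY = "in_assembly"


def _load_table(filename: str, key: str, value: str) -> dict[str, float]:
    with resources.files("dynhelix.data").joinpath(filename).open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df[key], df[value].astype(float)))


def default_radii_table() -> dict[str, float]:
    return _load_table("radii.csv", "name", "radius_A")


def default_max_sasa_table() -> dict[str, float]:
    """Empirical maximal per-residue SASA (theoretical Gly-X-Gly values), A^2."""
    return _load_table("max_sasa.csv", "residue", "max_sasa_A2")


@dataclass(frozen=True)
class SasaConfig:
    probe_radius: float = 1.4
    points_per_sphere: int = 960
    radii_table: dict = field(default_factory=default_radii_table)
    context: str = IN_ASSEMBLY

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.points_per_sphere < 92:
            raise ValueError("points_per_sphere must be >= 92")
        if self.context not in (ISOLATED_MONOMER, IN_ASSEMBLY):
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class SasaRecord:
    monomer_id: str
    residue_number: int
    sasa_A2: float
    normalized: float


def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (Fibonacci) unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def resolve_radii(monomer: MonomerModel, table: dict[str, float]) -> np.ndarray:
    """Per-particle radii: explicit > name table > leading-element fallback."""
    out = np.empty(monomer.n_atoms)
    for k, name in enumerate(monomer.atom_names):
        if monomer.radii is not None and np.isfinite(monomer.radii[k]):
            out[k] = monomer.radii[k]
            continue
        r = table.get(name)
        if r is None:
            stripped = name.lstrip(string.digits)
            r = table.get(stripped[:1]) if stripped else None
        if r is None:
            raise RadiiTableError(
                f"no radius for atom/bead {name!r} "
                f"(residue {monomer.residue_numbers[k]} of {monomer.monomer_id})"
            )
        out[k] = r
    return out


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    points_per_sphere: int = 960,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA (A^2) for ``subset`` atoms (all by default).

    All atoms in ``coords`` act as occluders; only the areas of ``subset``
    atoms are computed and returned (in subset order).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if subset is None:
        subset = np.arange(len(coords))
    pts = sphere_points(points_per_sphere)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    rmax = inflated.max() if len(radii) else 0.0
    areas = np.empty(len(subset))
    for k, i in enumerate(np.asarray(subset, dtype=int)):
        ri = inflated[i]
        nbr = tree.query_ball_point(coords[i], ri + rmax)
        nbr = np.array([j for j in nbr if j != i], dtype=int)
        # keep only spheres that can actually intersect atom i's inflated sphere
        if nbr.size:
            d = np.linalg.norm(coords[nbr] - coords[i], axis=1)
            nbr = nbr[d < ri + inflated[nbr]]
        surface = coords[i] + ri * pts
        if nbr.size == 0:
            frac = 1.0
        else:
            d2 = ((surface[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        areas[k] = 4.0 * np.pi * ri * ri * frac
    return areas


def _assembly_arrays(frame: OligomerFrame, config: SasaConfig):
    coords, radii, owners = [], [], []
    for m in frame.monomers:
        coords.append(m.coords)
        radii.append(resolve_radii(m, config.radii_table))
        owners.extend([m.monomer_id] * m.n_atoms)
    return np.concatenate(coords), np.concatenate(radii), owners


def residue_sasa(
    frame: OligomerFrame,
    monomer_id: str,
    residue_number: int,
    config: SasaConfig = SasaConfig(),
    max_sasa_table: dict[str, float] | None = None,
) -> SasaRecord:
    """SASA of one residue, in assembly context or on the isolated monomer."""
    mono = frame.monomer(monomer_id)
    local_idx = mono.select_residues([residue_number])
    if local_idx.size == 0:
        raise SelectionError(f"residue {residue_number} absent from monomer {monomer_id}")
    if config.context == IN_ASSEMBLY:
        offset = 0
        for m in frame.monomers:
            if m.monomer_id == monomer_id:
                break
            offset += m.n_atoms
        coords, radii, _ = _assembly_arrays(frame, config)
        subset = local_idx + offset
    else:
        coords = mono.coords
        radii = resolve_radii(mono, config.radii_table)
        subset = local_idx
    areas = shrake_rupley(
        coords, radii, config.probe_radius, config.points_per_sphere, subset=subset
    )
    total = float(areas.sum())
    table = max_sasa_table or default_max_sasa_table()
    resname = mono.residue_name_of(residue_number)
    max_sasa = table.get(resname)
    normalized = total / max_sasa if max_sasa else float("nan")
    if max_sasa and normalized > 1.5:
        log.warning(
            "normalized SASA %.2f > 1.5 for %s %d (%s): check radii/max-SASA tables",
            normalized, resname, residue_number, monomer_id,
        )
    return SasaRecord(monomer_id, residue_number, total, normalized)


def sasa_profile(
    trajectory: Trajectory,
    selection,
    config: SasaConfig = SasaConfig(),
    window: WindowSpec | None = None,
    max_sasa_table: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-frame residue SASA for a selection, plus per-monomer window means.

    ``selection`` is ``(monomer_ids, residue_number)``; ``monomer_ids`` may be
    ``"all"``.  Returns a tidy frame with columns monomer_id, residue_number,
    frame_index, sasa_A2, normalized; window means carry frame_index == -1 and
    are also retrievable by pivoting on it.
    """
    traj = select_window(trajectory, window) if window is not None else trajectory
    if not traj.frames:
        raise WindowError("empty window")
    monomer_ids, residue_number = selection
    if monomer_ids == "all":
        monomer_ids = traj.monomer_ids
    table = max_sasa_table or default_max_sasa_table()
    rows = []
    for frame in traj.frames:
        if config.context == IN_ASSEMBLY:
            # one assembly array per frame, shared across the selected monomers
            coords, radii, _ = _assembly_arrays(frame, config)
            offsets, off = {}, 0
            for m in frame.monomers:
                offsets[m.monomer_id] = off
                off += m.n_atoms
            for mid in monomer_ids:
                mono = frame.monomer(mid)
                local_idx = mono.select_residues([residue_number])
                if local_idx.size == 0:
                    raise SelectionError(f"residue {residue_number} absent from monomer {mid}")
                areas = shrake_rupley(
                    coords, radii, config.probe_radius, config.points_per_sphere,
                    subset=local_idx + offsets[mid],
                )
                total = float(areas.sum())
                max_sasa = table.get(mono.residue_name_of(residue_number))
                normalized = total / max_sasa if max_sasa else float("nan")
                rows.append((mid, residue_number, frame.frame_index, total, normalized))
            continue
        for mid in monomer_ids:
            rec = residue_sasa(frame, mid, residue_number, config, max_sasa_table)
            rows.append((mid, residue_number, frame.frame_index, rec.sasa_A2, rec.normalized))
    df = pd.DataFrame(
        rows, columns=["monomer_id", "residue_number", "frame_index", "sasa_A2", "normalized"]
    )
    means = (
        df.groupby("monomer_id", sort=False)[["sasa_A2", "normalized"]].mean().reset_index()
    )
    means.insert(1, "residue_number", residue_number)
    means.insert(2, "frame_index", -1)
    return pd.concat([df, means], ignore_index=True)
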