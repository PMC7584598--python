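"""Assembly topology: rungs, tetramers, neighbors and cross-rung G-G pairs.

Monomers are ordered along the helical path (axial position, then azimuth
about the helix axis, with the monomer id as a deterministic tie-break).
Rung index is the number of full turns of accumulated azimuth; consecutive
blocks of four monomers along the path form tetramers — a 56-monomer helix
therefore has exactly 14 of them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import TopologyError
from .structures import DomainMap, OligomerFrame


@dataclass
class AssemblyTopology:
    rung_of: dict[str, int]
    tetramer_of: dict[str, int]
    within_rung_neighbors: dict[str, list[str]]
    gg_partners: list[tuple[str, str]]
    #: monomer ids ordered along the helical path (axial, then azimuth)
    chain_order: list[str] = field(default_factory=list)

    @property
    def n_tetramers(self) -> int:
        return len(set(self.tetramer_of.values()))

    @property
    def n_rungs(self) -> int:
        return len(set(self.rung_of.values()))

    def path_neighbor_pairs(self) -> list[tuple[str, str]]:
        """Consecutive monomer pairs along the helical path (any rung)."""
        return list(zip(self.chain_order, self.chain_order[1:]))


def _monomer_com(monomer) -> np.ndarray:
    w = monomer.masses
    if w is None:
        return monomer.coords.mean(axis=0)
    return (monomer.coords * w[:, None]).sum(axis=0) / w.sum()


def _azimuth_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic in-plane basis: cross with the least-aligned world axis
    ref = np.zeros(3)
    ref[np.argmin(np.abs(axis))] = 1.0
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def assign_topology(
    frame: OligomerFrame,
    helix_axis,
    tetramer_size: int = 4,
    *,
    contact_cutoff: float = 6.0,
    domain_map: DomainMap | None = None,
) -> AssemblyTopology:
    """Establish rungs, tetramers, within-rung neighbors and G-G pairs.

    ``gg_partners`` are cross-rung monomer pairs whose G-domain particles come
    within ``contact_cutoff`` (Angstrom) of each other; this contact-based
    definition reconstructs the G-G interface pairs used for bending-asymmetry
    statistics.
    """
    monomers = frame.monomers
    if len(monomers) % tetramer_size != 0:
        raise TopologyError(
            f"{len(monomers)} monomers not divisible by tetramer size {tetramer_size}"
        )
    dmap = domain_map or DomainMap()

    axis = np.asarray(helix_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise TopologyError("helix_axis must be a nonzero vector")
    axis = axis / norm
    u, v = _azimuth_basis(axis)

    coms = np.array([_monomer_com(m) for m in monomers])
    center = coms.mean(axis=0)
    rel = coms - center
    axial = rel @ axis
    azimuth = np.arctan2(rel @ v, rel @ u)

    order = sorted(
        range(len(monomers)),
        key=lambda i: (axial[i], azimuth[i], monomers[i].monomer_id),
    )
    ordered_ids = [monomers[i].monomer_id for i in order]

    # accumulated (unwrapped) azimuth along the path; each step in [0, 2pi)
    acc = 0.0
    rung_of = {ordered_ids[0]: 0}
    for prev, cur in zip(order, order[1:]):
        step = (azimuth[cur] - azimuth[prev]) % (2 * np.pi)
        acc += step
        rung_of[monomers[cur].monomer_id] = int(acc // (2 * np.pi))

    tetramer_of = {
        mid: pos // tetramer_size for pos, mid in enumerate(ordered_ids)
    }

    within: dict[str, list[str]] = {mid: [] for mid in ordered_ids}
    for a, b in zip(ordered_ids, ordered_ids[1:]):
        if rung_of[a] == rung_of[b]:
            within[a].append(b)
            within[b].append(a)

    gg = _gg_partners(frame, rung_of, dmap, contact_cutoff)
    return AssemblyTopology(
        rung_of=rung_of,
        tetramer_of=tetramer_of,
        within_rung_neighbors=within,
        gg_partners=gg,
        chain_order=ordered_ids,
    )


def _gg_partners(frame, rung_of, dmap, cutoff) -> list[tuple[str, str]]:
    coords, owner = [], []
    for i, m in enumerate(frame.monomers):
        idx = m.select_ranges(dmap.g_domain)
        if idx.size:
            coords.append(m.coords[idx])
            owner.extend([i] * idx.size)
    if not coords:
        return []
    coords = np.concatenate(coords)
    owner = np.asarray(owner)
    pairs = cKDTree(coords).query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size == 0:
        return []
    found = set()
    ids = [m.monomer_id for m in frame.monomers]
    for ia, ib in zip(owner[pairs[:, 0]], owner[pairs[:, 1]]):
        if ia == ib:
            continue
        a, b = ids[ia], ids[ib]
        if rung_of[a] == rung_of[b]:
            continue
        found.add((a, b) if a < b else (b, a))
    return sorted(found)
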