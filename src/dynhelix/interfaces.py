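"""Monomer-monomer interfaces: contacts, classification, area, occupancy, bonds.

A residue of monomer A is *in contact* with monomer B when any of its
particles lies within 6 Angstrom (inclusive) of any particle of B.  The four
interface classes of the dynamin helix are assigned from the domains of the
contacting residues:

* **GG** — cross-rung contact dominated by G-domain residues on both sides.
* **IF1** — stalk of one monomer against the BSE of the other (the region
  around residues 330 and 692).
* **IF2** — the central crisscross stalk-stalk contact (alpha-S2..S4
  segments, residues ~455-495 / 660-690).
* **IF3** — stalk-stalk contact dominated by the L1N^S loop.

Interface *area* is, by default, the summed in-assembly SASA of the contact
residues ("the area included by amino acids falling within 6 Angstrom"); a
buried-surface mode (isolated-monomer SASA minus in-pair SASA) is also
provided.  *Occupancy* of a residue in an interface type is the fraction of
(instance x frame) observations of that type in which the residue is a
contact residue.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ResolutionError, SelectionError, TopologyError
from .sasa import IN_ASSEMBLY, ISOLATED_MONOMER, SasaConfig, resolve_radii, shrake_rupley
from .structures import DomainMap, FULL_ATOM, MonomerModel, OligomerFrame
from .topology import AssemblyTopology

log = logging.getLogger(__name__)

GG = "GG"
IF1 = "IF1"
IF2 = "IF2"
IF3 = "IF3"
R465_BSE = "R465_BSE"
UNCLASSIFIED = "unclassified"

EXPOSED_SUM = "exposed_sum"
BURIED = "buried"


@dataclass(frozen=True)
class InterfaceConfig:
    contact_cutoff: float = 6.0
    distance_mode: str = "closest_particle"
    area_mode: str = EXPOSED_SUM
    #: fraction of contact residues that must fall in a domain for majority rules
    domain_majority: float = 0.5

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.distance_mode != "closest_particle":
            raise ValueError("only closest_particle distance is defined")
        if self.area_mode not in (EXPOSED_SUM, BURIED):
            raise ValueError(f"unknown area_mode {self.area_mode!r}")


@dataclass
class InterfaceInstance:
    pair: tuple[str, str]
    itype: str
    residues_a: frozenset[int]
    residues_b: frozenset[int]
    area_A2: float
    frame_index: int

    @property
    def all_residues(self) -> frozenset[int]:
        return self.residues_a | self.residues_b


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def find_contact_residues(
    frame: OligomerFrame,
    monomer_a: str,
    monomer_b: str,
    config: InterfaceConfig = InterfaceConfig(),
) -> tuple[frozenset[int], frozenset[int]]:
    """Residues of each monomer within the contact cutoff of the other.

    Minimum inter-particle distance, inclusive at the cutoff.  Exact (KD-tree
    accelerated but equivalent to the all-pairs rule).
    """
    ma = frame.monomer(monomer_a)
    mb = frame.monomer(monomer_b)
    tree_a = cKDTree(ma.coords)
    tree_b = cKDTree(mb.coords)
    pairs = tree_a.query_ball_tree(tree_b, r=config.contact_cutoff)
    res_a, res_b = set(), set()
    for ia, js in enumerate(pairs):
        if js:
            res_a.add(int(ma.residue_numbers[ia]))
            res_b.update(int(mb.residue_numbers[j]) for j in js)
    return frozenset(res_a), frozenset(res_b)


def _restrict_contacts(ma, mb, residues_a, residues_b, cutoff):
    """Index pairs (into ma, mb atoms) within cutoff, restricted to residue sets."""
    ia = ma.select_residues(residues_a) if residues_a is not None else np.arange(ma.n_atoms)
    ib = mb.select_residues(residues_b) if residues_b is not None else np.arange(mb.n_atoms)
    if ia.size == 0 or ib.size == 0:
        return ia[:0], ib[:0]
    pairs = cKDTree(ma.coords[ia]).query_ball_tree(cKDTree(mb.coords[ib]), r=cutoff)
    out_a, out_b = [], []
    for k, js in enumerate(pairs):
        for j in js:
            out_a.append(ia[k])
            out_b.append(ib[j])
    return np.asarray(out_a, dtype=int), np.asarray(out_b, dtype=int)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _domain_fraction(residues: Iterable[int], dmap: DomainMap, domain: str) -> float:
    residues = list(residues)
    if not residues:
        return 0.0
    hits = sum(1 for r in residues if dmap.domain_of(r) == domain)
    return hits / len(residues)


def _in_ranges(r: int, ranges) -> bool:
    return any(lo <= r <= hi for lo, hi in ranges)


def classify_interface(
    frame: OligomerFrame,
    pair: tuple[str, str],
    topology: AssemblyTopology,
    dmap: DomainMap,
    contacts: tuple[frozenset[int], frozenset[int]],
    config: InterfaceConfig = InterfaceConfig(),
) -> str:
    """Assign one of GG / IF1 / IF2 / IF3 / unclassified to a contacting pair."""
    res_a, res_b = contacts
    if not res_a or not res_b:
        raise SelectionError(f"cannot classify pair {pair}: empty contact set")
    thr = config.domain_majority
    cross_rung = topology.rung_of[pair[0]] != topology.rung_of[pair[1]]
    if (
        cross_rung
        and _domain_fraction(res_a, dmap, "g_domain") >= thr
        and _domain_fraction(res_b, dmap, "g_domain") >= thr
    ):
        return GG
    stalk_a = _domain_fraction(res_a, dmap, "stalk")
    stalk_b = _domain_fraction(res_b, dmap, "stalk")
    bse_a = _domain_fraction(res_a, dmap, "bse")
    bse_b = _domain_fraction(res_b, dmap, "bse")
    if (stalk_a >= thr and bse_b >= thr) or (stalk_b >= thr and bse_a >= thr):
        return IF1
    if stalk_a >= thr and stalk_b >= thr:
        both = list(res_a | res_b)
        n_if2 = sum(1 for r in both if _in_ranges(r, dmap.if2_segments))
        n_l1ns = sum(1 for r in both if _in_ranges(r, dmap.l1ns))
        if n_if2 and n_if2 >= n_l1ns:
            return IF2
        if n_l1ns:
            return IF3
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# area
# ---------------------------------------------------------------------------

def _residue_set_sasa(frame_monomers: Sequence[MonomerModel], wanted, sasa_config):
    """Summed SASA of (monomer_id -> residue set) within the given assembly."""
    coords, radii, subset, owner = [], [], [], []
    offset = 0
    for m in frame_monomers:
        coords.append(m.coords)
        radii.append(resolve_radii(m, sasa_config.radii_table))
        res = wanted.get(m.monomer_id)
        if res:
            idx = m.select_residues(res)
            subset.append(idx + offset)
        offset += m.n_atoms
    if not subset:
        return 0.0
    areas = shrake_rupley(
        np.concatenate(coords),
        np.concatenate(radii),
        sasa_config.probe_radius,
        sasa_config.points_per_sphere,
        subset=np.concatenate(subset),
    )
    return float(areas.sum())


def interface_area(
    frame: OligomerFrame,
    instance: InterfaceInstance,
    sasa_config: SasaConfig = SasaConfig(),
    area_mode: str = EXPOSED_SUM,
) -> float:
    """Area (A^2) of an interface given its contact residue sets.

    ``exposed_sum``: summed in-assembly SASA over the union of contact
    residues of both monomers.  ``buried``: sum over the same residues of
    (isolated-monomer SASA - in-pair SASA), clipped at quadrature zero.
    """
    a, b = instance.pair
    if not instance.residues_a and not instance.residues_b:
        return 0.0
    wanted = {a: instance.residues_a, b: instance.residues_b}
    if area_mode == EXPOSED_SUM:
        return _residue_set_sasa(frame.monomers, wanted, sasa_config)
    pair_monomers = [frame.monomer(a), frame.monomer(b)]
    in_pair = _residue_set_sasa(pair_monomers, wanted, sasa_config)
    isolated = sum(
        _residue_set_sasa([frame.monomer(mid)], {mid: wanted[mid]}, sasa_config)
        for mid in (a, b)
    )
    return max(isolated - in_pair, 0.0)


def build_interface_instance(
    frame: OligomerFrame,
    pair: tuple[str, str],
    topology: AssemblyTopology,
    dmap: DomainMap,
    config: InterfaceConfig = InterfaceConfig(),
    sasa_config: SasaConfig | None = None,
    compute_area: bool = True,
) -> InterfaceInstance | None:
    """Contacts + classification + area for one candidate pair (None if no contact)."""
    contacts = find_contact_residues(frame, *pair, config)
    if not contacts[0]:
        return None
    itype = classify_interface(frame, pair, topology, dmap, contacts, config)
    inst = InterfaceInstance(
        pair=pair,
        itype=itype,
        residues_a=contacts[0],
        residues_b=contacts[1],
        area_A2=0.0,
        frame_index=frame.frame_index,
    )
    if compute_area:
        inst.area_A2 = interface_area(
            frame, inst, sasa_config or SasaConfig(), config.area_mode
        )
    return inst


def catalog_interfaces(
    frame: OligomerFrame,
    topology: AssemblyTopology,
    dmap: DomainMap | None = None,
    config: InterfaceConfig = InterfaceConfig(),
    sasa_config: SasaConfig | None = None,
    compute_area: bool = True,
) -> list[InterfaceInstance]:
    """All interface instances among path-neighbor and G-G candidate pairs."""
    dmap = dmap or DomainMap()
    candidates = list(dict.fromkeys(topology.path_neighbor_pairs() + topology.gg_partners))
    out = []
    for pair in candidates:
        inst = build_interface_instance(
            frame, pair, topology, dmap, config, sasa_config, compute_area
        )
        if inst is not None:
            out.append(inst)
    return out


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTable:
    """occupancy fraction and raw counts per (interface type, residue)."""

    fractions: dict[tuple[str, int], float] = field(default_factory=dict)
    counts: dict[tuple[str, int], int] = field(default_factory=dict)
    observations: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (itype, res, self.fractions[(itype, res)], self.counts[(itype, res)])
            for itype, res in sorted(self.fractions)
        ]
        return pd.DataFrame(rows, columns=["itype", "residue_number", "fraction", "count"])


def occupancy(instances: Iterable[InterfaceInstance]) -> OccupancyTable:
    """Residue occupancy per interface type over (instance x frame) observations."""
    table = OccupancyTable()
    instances = list(instances)
    if not instances:
        log.warning("occupancy: no interface instances observed")
        return table
    for inst in instances:
        table.observations[inst.itype] = table.observations.get(inst.itype, 0) + 1
        for res in inst.all_residues:
            key = (inst.itype, res)
            table.counts[key] = table.counts.get(key, 0) + 1
    for (itype, res), c in table.counts.items():
        table.fractions[(itype, res)] = c / table.observations[itype]
    return table


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges (full-atom only)
# ---------------------------------------------------------------------------

#: donor atom -> covalently bonded antecedent (for the hydrogen-free angle proxy)
DEFAULT_DONORS = {
    "N": "CA",
    "OG": "CB", "OG1": "CB", "OH": "CZ",
    "ND2": "CG", "NE2": "CD",
    "NZ": "CE", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "ND1": "CG", "NE1": "CD1",
}
DEFAULT_ACCEPTORS = (
    "O", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1",
)


@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.5
    min_angle_deg: float = 120.0
    donors: dict = field(default_factory=lambda: dict(DEFAULT_DONORS))
    acceptors: tuple = DEFAULT_ACCEPTORS

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0 < self.min_angle_deg <= 180:
            raise ValueError("min_angle_deg must be in (0, 180]")


BASIC_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class SaltBridgeCriteria:
    max_distance: float = 4.0
    basic_atoms: dict = field(default_factory=lambda: dict(BASIC_ATOMS))
    acidic_atoms: dict = field(default_factory=lambda: dict(ACIDIC_ATOMS))

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


def _require_full_atom(frame: OligomerFrame, what: str):
    if frame.resolution != FULL_ATOM:
        raise ResolutionError(f"{what} requires full-atom input, got coarse-grained")


def _named_atom(monomer: MonomerModel, residue_number: int, name: str) -> int | None:
    for k in np.flatnonzero(monomer.residue_numbers == residue_number):
        if monomer.atom_names[k] == name:
            return int(k)
    return None


def _attached_hydrogens(monomer: MonomerModel, donor_idx: int) -> list[int]:
    res = monomer.residue_numbers[donor_idx]
    out = []
    for k in np.flatnonzero(monomer.residue_numbers == res):
        if monomer.atom_names[k].startswith("H"):
            if np.linalg.norm(monomer.coords[k] - monomer.coords[donor_idx]) < 1.25:
                out.append(int(k))
    return out


def _hbond_pairs_one_way(md, ma_, criteria, res_d, res_a):
    """Count donor(md)->acceptor(ma_) bonds, restricted to residue sets."""
    from .geometry import angle_between

    donors = [
        (k, criteria.donors[md.atom_names[k]])
        for k in range(md.n_atoms)
        if md.atom_names[k] in criteria.donors
        and (res_d is None or md.residue_numbers[k] in res_d)
    ]
    acc = [
        k
        for k in range(ma_.n_atoms)
        if ma_.atom_names[k] in criteria.acceptors
        and (res_a is None or ma_.residue_numbers[k] in res_a)
    ]
    if not donors or not acc:
        return set()
    acc_coords = ma_.coords[acc]
    tree = cKDTree(acc_coords)
    bonds = set()
    for k, antecedent in donors:
        near = tree.query_ball_point(md.coords[k], criteria.max_distance)
        if not near:
            continue
        hydrogens = _attached_hydrogens(md, k)
        ant_idx = _named_atom(md, int(md.residue_numbers[k]), antecedent)
        for j in near:
            a_pos = acc_coords[j]
            ok = True
            if hydrogens:
                ok = any(
                    angle_between(md.coords[k] - md.coords[h], a_pos - md.coords[h])
                    >= criteria.min_angle_deg
                    for h in hydrogens
                )
            elif ant_idx is not None:
                ok = (
                    angle_between(md.coords[ant_idx] - md.coords[k], a_pos - md.coords[k])
                    >= criteria.min_angle_deg
                )
            if ok:
                bonds.add((int(md.residue_numbers[k]), md.atom_names[k],
                           int(ma_.residue_numbers[acc[j]]), ma_.atom_names[acc[j]]))
    return bonds


def count_hbonds(
    frame: OligomerFrame,
    pair: tuple[str, str],
    criteria: HBondCriteria = HBondCriteria(),
    restrict_to: str | None = None,
    topology: AssemblyTopology | None = None,
    dmap: DomainMap | None = None,
    config: InterfaceConfig = InterfaceConfig(),
) -> int:
    """Cross-monomer hydrogen bonds satisfying the geometric criteria.

    With explicit hydrogens the donor-H...acceptor angle is tested; otherwise
    a donor-antecedent angle proxy is used (hydrogen-free mode).
    ``restrict_to`` limits both sides to the residues of the named interface
    type (contacts are recomputed for the pair).
    """
    _require_full_atom(frame, "count_hbonds")
    res_a = res_b = None
    if restrict_to is not None:
        res_a, res_b = _interface_residues(frame, pair, restrict_to, topology, dmap, config)
    ma = frame.monomer(pair[0])
    mb = frame.monomer(pair[1])
    fwd = _hbond_pairs_one_way(ma, mb, criteria, res_a, res_b)
    rev = _hbond_pairs_one_way(mb, ma, criteria, res_b, res_a)
    return len(fwd) + len(rev)


def _interface_residues(frame, pair, itype, topology, dmap, config):
    contacts = find_contact_residues(frame, *pair, config)
    if topology is not None:
        found = classify_interface(frame, pair, topology, dmap or DomainMap(), contacts, config)
        if found != itype:
            log.warning("pair %s classified %s, not requested %s", pair, found, itype)
    return contacts


def count_salt_bridges(
    frame: OligomerFrame,
    pair: tuple[str, str],
    criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
) -> int:
    """Cross-monomer basic/acidic contacts, one bridge per residue pair."""
    _require_full_atom(frame, "count_salt_bridges")
    ma = frame.monomer(pair[0])
    mb = frame.monomer(pair[1])

    def charged(m, table):
        idx = [
            k
            for k in range(m.n_atoms)
            if m.atom_names[k] in table.get(m.residue_names[k], ())
        ]
        return np.asarray(idx, dtype=int)

    # one bridge per (residue of monomer a, residue of monomer b) pair
    bridges = set()
    for mx, my, a_is_basic in ((ma, mb, True), (mb, ma, False)):
        basic = charged(mx, criteria.basic_atoms)
        acidic = charged(my, criteria.acidic_atoms)
        if basic.size == 0 or acidic.size == 0:
            continue
        tree = cKDTree(my.coords[acidic])
        for k in basic:
            for j in tree.query_ball_point(mx.coords[k], criteria.max_distance):
                rx = int(mx.residue_numbers[k])
                ry = int(my.residue_numbers[acidic[j]])
                bridges.add((rx, ry) if a_is_basic else (ry, rx))
    return len(bridges)


# ---------------------------------------------------------------------------
# residue 465 <-> neighbor BSE
# ---------------------------------------------------------------------------

def residue465_bse_interaction(
    frame: OligomerFrame,
    topology: AssemblyTopology,
    dmap: DomainMap | None = None,
    config: InterfaceConfig = InterfaceConfig(),
    sasa_config: SasaConfig | None = None,
    compute_area: bool = True,
) -> list[InterfaceInstance]:
    """Contacts of residue 465 of each monomer with its neighbor's BSE.

    For every ordered within-rung neighbor pair (i, j): contacts between
    residue 465 of i and BSE residues of j, with the interaction area of the
    contacting residues.  Pairs without 465-BSE contact yield an empty
    instance with zero area.
    """
    dmap = dmap or DomainMap()
    out = []
    site = dmap.mutation_site
    for mid in frame.monomer_ids:
        neighbors = topology.within_rung_neighbors.get(mid)
        if neighbors is None:
            raise TopologyError(f"monomer {mid} missing from topology")
        mono = frame.monomer(mid)
        if not np.any(mono.residue_numbers == site):
            raise SelectionError(f"residue {site} absent from monomer {mid}")
        for nb in neighbors:
            other = frame.monomer(nb)
            bse_res = set(
                int(r) for r in other.residue_numbers[other.select_ranges(dmap.bse)]
            )
            ia, ib = _restrict_contacts(mono, other, [site], bse_res, config.contact_cutoff)
            res_b = frozenset(int(other.residue_numbers[k]) for k in ib)
            res_a = frozenset({site}) if len(ia) else frozenset()
            inst = InterfaceInstance(
                pair=(mid, nb),
                itype=R465_BSE,
                residues_a=res_a,
                residues_b=res_b,
                area_A2=0.0,
                frame_index=frame.frame_index,
            )
            if compute_area and res_b:
                inst.area_A2 = interface_area(frame, inst, sasa_config or SasaConfig())
            out.append(inst)
    return out


# ---------------------------------------------------------------------------
# intra-monomer contacts
# ---------------------------------------------------------------------------

def intramonomer_contacts(
    frame: OligomerFrame,
    monomer_id: str,
    residue_number: int,
    config: InterfaceConfig = InterfaceConfig(),
    exclude_neighbors: int = 1,
) -> frozenset[int]:
    """Residues of the same monomer within the cutoff of the query residue.

    Sequence neighbors within ``exclude_neighbors`` of the query (and the
    query itself) are excluded; pass ``exclude_neighbors=0`` to keep direct
    sequence neighbors.
    """
    mono = frame.monomer(monomer_id)
    idx = mono.select_residues([residue_number])
    if idx.size == 0:
        raise SelectionError(f"residue {residue_number} absent from monomer {monomer_id}")
    tree = cKDTree(mono.coords)
    near = set()
    for k in idx:
        for j in tree.query_ball_point(mono.coords[k], config.contact_cutoff):
            near.add(int(mono.residue_numbers[j]))
    return frozenset(
        r for r in near if abs(r - residue_number) > exclude_neighbors
    )


def instances_to_frame(instances: Iterable[InterfaceInstance]) -> pd.DataFrame:
    rows = [
        (
            inst.pair[0],
            inst.pair[1],
            inst.itype,
            inst.frame_index,
            inst.area_A2,
            len(inst.all_residues),
        )
        for inst in instances
    ]
    return pd.DataFrame(
        rows, columns=["monomer_a", "monomer_b", "itype", "frame_index", "area_A2", "n_residues"]
    )
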