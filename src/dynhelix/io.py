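"""Reading and writing multi-model structure ensembles (mmCIF / PDB).

Each model of the file becomes one :class:`~dynhelix.structures.OligomerFrame`;
chains (``auth_asym_id`` in mmCIF) become monomers.  Coarse-grained ensembles
are detected from bead names (``BB``, ``SC1``..``SC4`` by default).  56-monomer
assemblies should be written as mmCIF: classic PDB chain ids are a single
character, capping a PDB file at 62 monomers.
"""
from __future__ import annotations

import os
import string
from typing import Sequence

import gemmi
import numpy as np

from .errors import CapacityError, ConsistencyError, FormatError
from .structures import (
    CG_BEAD_NAMES,
    COARSE_GRAINED,
    FULL_ATOM,
    R465W,
    WT,
    MonomerModel,
    OligomerFrame,
    Trajectory,
)

_PDB_CHAIN_CHARS = set(string.ascii_uppercase + string.ascii_lowercase + string.digits)


def _element_of(atom_name: str) -> gemmi.Element:
    stripped = atom_name.lstrip(string.digits)
    return gemmi.Element(stripped[:1] if stripped else "C")


def _genotype_of(residue_numbers: np.ndarray, residue_names: Sequence[str]) -> str:
    idx = np.flatnonzero(residue_numbers == 465)
    if idx.size and residue_names[idx[0]] == "TRP":
        return R465W
    return WT


def read_structure(path, format: str = "auto", cg_bead_names=CG_BEAD_NAMES) -> Trajectory:
    """Read a (multi-model) mmCIF or PDB file into a :class:`Trajectory`.

    Monomer ids come from the chain identifier; the coarse-grained flag is set
    when every atom name matches ``cg_bead_names``.  Genotype is inferred from
    residue 465 (TRP -> R465W).
    """
    path = os.fspath(path)
    try:
        if format == "auto":
            st = gemmi.read_structure(path)
        elif format == "pdb":
            st = gemmi.read_pdb(path)
        elif format == "mmcif":
            doc = gemmi.cif.read(path)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")

    bead_set = set(cg_bead_names)
    frames = []
    all_names: set[str] = set()
    ref_ids: list[str] | None = None
    for imodel, model in enumerate(st):
        monomers = []
        for chain in model:
            atom_names, res_names, res_nums, coords, serials = [], [], [], [], []
            for res in chain:
                for atom in res:
                    atom_names.append(atom.name)
                    res_names.append(res.name)
                    res_nums.append(res.seqid.num)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    serials.append(atom.serial)
            all_names.update(atom_names)
            res_nums = np.asarray(res_nums, dtype=int)
            monomers.append(
                dict(
                    monomer_id=chain.name,
                    atom_names=atom_names,
                    residue_names=res_names,
                    residue_numbers=res_nums,
                    coords=np.asarray(coords, dtype=float),
                    serials=serials,
                    genotype=_genotype_of(res_nums, res_names),
                )
            )
        ids = [m["monomer_id"] for m in monomers]
        if ref_ids is None:
            ref_ids = ids
        elif ids != ref_ids:
            raise ConsistencyError(
                f"{path}: monomer set differs between model 1 ({ref_ids}) "
                f"and model {imodel + 1} ({ids})"
            )
        frames.append(monomers)

    coarse = bool(all_names) and all_names <= bead_set
    resolution = COARSE_GRAINED if coarse else FULL_ATOM

    out_frames = []
    for i, monomers in enumerate(frames):
        models = []
        for m in monomers:
            masses = None
            if not coarse:
                masses = [_element_of(nm).weight for nm in m["atom_names"]]
            models.append(
                MonomerModel(
                    m["monomer_id"],
                    m["genotype"],
                    atom_names=m["atom_names"],
                    residue_names=m["residue_names"],
                    residue_numbers=m["residue_numbers"],
                    coords=m["coords"],
                    serials=m["serials"],
                    masses=masses,
                )
            )
        out_frames.append(OligomerFrame(frame_index=i, monomers=models, resolution=resolution))
    return Trajectory(frames=out_frames, metadata={"source": path})


def write_structure(trajectory: Trajectory, path, format: str = "mmcif") -> None:
    """Write a trajectory as a multi-model mmCIF or PDB file.

    ``read_structure`` inverts this up to 1e-3 Angstrom coordinate precision.
    """
    path = os.fspath(path)
    if format not in ("mmcif", "pdb"):
        raise ValueError(f"unknown format {format!r}")
    ids = trajectory.monomer_ids
    if format == "pdb":
        if len(ids) > 62:
            raise CapacityError(
                f"{len(ids)} monomers exceed the 62 single-character chain ids of the "
                "PDB format; write mmCIF instead"
            )
        bad = [i for i in ids if len(i) != 1 or i not in _PDB_CHAIN_CHARS]
        if bad:
            raise CapacityError(
                f"monomer ids {bad} are not single alphanumeric characters; "
                "rename monomers or write mmCIF"
            )

    st = gemmi.Structure()
    st.name = "dynhelix"
    for frame in trajectory.frames:
        model = gemmi.Model(frame.frame_index + 1)
        for mono in frame.monomers:
            chain = gemmi.Chain(mono.monomer_id)
            res = None
            current_num = None
            for k in range(mono.n_atoms):
                num = int(mono.residue_numbers[k])
                if num != current_num:
                    if res is not None:
                        chain.add_residue(res)
                    res = gemmi.Residue()
                    res.name = mono.residue_names[k]
                    res.seqid = gemmi.SeqId(num, " ")
                    current_num = num
                atom = gemmi.Atom()
                atom.name = mono.atom_names[k]
                atom.serial = int(mono.serials[k])
                atom.pos = gemmi.Position(*mono.coords[k])
                atom.element = _element_of(mono.atom_names[k])
                res.add_atom(atom)
            if res is not None:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    if format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)
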