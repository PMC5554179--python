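"""File round-trip I/O: extended XYZ with a JSON topology sidecar, minimal PDB.

Configurations are serialized as extended-XYZ frames whose comment line
carries the box ("Lattice"), periodicity, hydration bookkeeping and coupling
state; per-particle columns hold species name, position, water flag and
residue label.  Positions are printed with 17 significant digits, so a
write-then-read round-trip is bit-exact for float64.  The topology (species
table, bonds, crosslinks, tethers) lives in a JSON sidecar written once per
trajectory, since it refers only to the matrix beads and never changes as
waters come and go.

PDB input (ATOM/HETATM/CRYST1 records) is read through biotite and mapped to
analysis frames: 1-based residue numbering becomes 0-based group labels, and
residues named HOH/WAT/SOL/TIP3 are flagged as water.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .analysis import Frame, WATER_RESIDUE
from .model import (Box, Configuration, HarmonicBonds, Species, Tethers,
                    Topology)

__all__ = ["write_frames", "read_frames", "topology_sidecar_path",
           "read_pdb_frames"]

_FMT = "%.17g"


def topology_sidecar_path(path) -> Path:
    return Path(path).with_suffix(".topology.json")


# -- extended XYZ ----------------------------------------------------------

def _species_to_dict(s: Species) -> dict:
    return {"name": s.name, "mass": s.mass, "epsilon": s.epsilon,
            "sigma": s.sigma, "affinity": s.affinity,
            "sasa_radius": s.sasa_radius}


def _bonds_to_dict(b: HarmonicBonds) -> dict:
    return {"pairs": b.pairs.tolist(), "k": b.k.tolist(), "r0": b.r0.tolist()}


def _bonds_from_dict(d: dict) -> HarmonicBonds:
    return HarmonicBonds(np.array(d["pairs"], dtype=np.int64).reshape(-1, 2),
                         k=np.array(d["k"]), r0=np.array(d["r0"]))


def write_frames(frames: Sequence[Configuration], path, write_sidecar=True) -> None:
    """Write one or more configurations as concatenated extended-XYZ frames."""
    path = Path(path)
    lines: List[str] = []
    for config in frames:
        L = config.box.lengths
        lattice = " ".join(_FMT % v for v in
                           [L[0], 0, 0, 0, L[1], 0, 0, 0, L[2]])
        pbc = " ".join("T" if p else "F" for p in config.box.periodic)
        cidx, lam = config.coupling_state()
        comment = (f'Lattice="{lattice}" '
                   f'Properties=species:S:1:pos:R:3:is_water:I:1:residue_id:I:1 '
                   f'pbc="{pbc}" coupling_index={cidx} coupling_lam={_FMT % lam}')
        lines.append(str(config.n_particles))
        lines.append(comment)
        names = [config.species[s].name for s in config.species_ids]
        rid = (config.residue_ids if config.residue_ids is not None
               else np.where(config.is_water, WATER_RESIDUE, 0))
        for k in range(config.n_particles):
            x, y, z = config.positions[k]
            lines.append(f"{names[k]} {_FMT % x} {_FMT % y} {_FMT % z} "
                         f"{int(config.is_water[k])} {int(rid[k])}")
    path.write_text("\n".join(lines) + "\n")
    if write_sidecar and frames:
        ref = frames[0]
        sidecar = {
            "species": [_species_to_dict(s) for s in ref.species],
            "chain_bonds": _bonds_to_dict(ref.topology.chain_bonds),
            "crosslinks": _bonds_to_dict(ref.topology.crosslinks),
            "tethers": {"indices": ref.topology.tethers.indices.tolist(),
                        "k": ref.topology.tethers.k.tolist(),
                        "anchors": ref.topology.tethers.anchors.tolist()},
        }
        topology_sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _load_sidecar(path):
    sc_path = topology_sidecar_path(path)
    if not sc_path.exists():
        return None, None
    d = json.loads(sc_path.read_text())
    species = [Species(**s) for s in d["species"]]
    topology = Topology(
        chain_bonds=_bonds_from_dict(d["chain_bonds"]),
        crosslinks=_bonds_from_dict(d["crosslinks"]),
        tethers=Tethers(np.array(d["tethers"]["indices"], dtype=np.int64),
                        k=np.array(d["tethers"]["k"]),
                        anchors=np.array(d["tethers"]["anchors"]).reshape(-1, 3)))
    return species, topology


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_PBC_RE = re.compile(r'pbc="([^"]+)"')
_KV_RE = re.compile(r'(\w+)=([^\s"]+)')


def read_frames(path) -> List[Configuration]:
    """Read extended-XYZ frames written by :func:`write_frames`.

    Malformed records raise with the offending line number.  If the topology
    sidecar is missing, frames get an empty topology and a species table
    reconstructed from the names in the file (unit parameters).
    """
    path = Path(path)
    species, topology = _load_sidecar(path)
    lines = path.read_text().splitlines()
    frames: List[Configuration] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError as err:
            raise ValueError(f"{path}:{ln + 1}: expected particle count") from err
        comment = lines[ln + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise ValueError(f"{path}:{ln + 2}: missing Lattice entry")
        lat = np.array(m.group(1).split(), dtype=float).reshape(3, 3)
        pbc_m = _PBC_RE.search(comment)
        periodic = ([t == "T" for t in pbc_m.group(1).split()]
                    if pbc_m else [True] * 3)
        kv = dict(_KV_RE.findall(comment))
        cidx = int(kv.get("coupling_index", -1))
        lam = float(kv.get("coupling_lam", 1.0))
        box = Box(np.diag(lat), periodic=periodic)
        names, pos, isw, rid = [], [], [], []
        for k in range(n):
            row = lines[ln + 2 + k].split()
            if len(row) != 6:
                raise ValueError(
                    f"{path}:{ln + 3 + k}: expected 6 columns, got {len(row)}")
            names.append(row[0])
            pos.append([float(v) for v in row[1:4]])
            isw.append(bool(int(row[4])))
            rid.append(int(row[5]))
        if species is None:
            uniq = sorted(set(names))
            frame_species = [Species(u, mass=1.0) for u in uniq]
        else:
            frame_species = species
        name_to_id = {s.name: i for i, s in enumerate(frame_species)}
        sid = np.array([name_to_id[nm] for nm in names], dtype=np.int64)
        coupling = (cidx, lam) if cidx >= 0 and lam < 1.0 else None
        frames.append(Configuration(
            np.array(pos), sid, np.array(isw, dtype=bool),
            topology if topology is not None else Topology(), box,
            frame_species, coupling=coupling,
            residue_ids=np.array(rid, dtype=np.int64), wrap=False))
        ln += 2 + n
    return frames


# -- minimal PDB (read-only, via biotite) ----------------------------------

_WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "SPC"}


def read_pdb_frames(path) -> List[Frame]:
    """Read ATOM/HETATM records of a PDB file into analysis frames.

    Coordinates stay in Angstrom; residue numbers are mapped to 0-based
    grouping labels, waters get the reserved label.  Boxless files fall back
    to a bounding, non-periodic box.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.stack_depth() == 0:
        raise ValueError(f"{path}: no models found")
    cell = pdb.get_structure(model=1).box
    frames = []
    for model in range(stack.stack_depth()):
        atoms = stack[model]
        coords = np.asarray(atoms.coord, dtype=np.float64)
        is_water = np.isin(np.char.upper(atoms.res_name.astype(str)),
                           list(_WATER_RESNAMES))
        rid = np.where(is_water, WATER_RESIDUE,
                       atoms.res_id.astype(np.int64) - 1)
        if cell is not None:
            box = Box(np.diag(np.asarray(cell).reshape(3, 3)))
        else:
            span = coords.max(axis=0) - coords.min(axis=0) + 10.0
            box = Box(span, periodic=[False] * 3)
        try:
            masses = np.array([struc.info.mass(e) or 12.0
                               for e in atoms.element])
        except Exception:
            masses = np.full(len(coords), 12.0)
        frames.append(Frame(positions=coords, is_water=is_water,
                            residue_ids=rid, box=box, masses=masses,
                            radii=np.full(len(coords), 1.5)))
    return frames
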