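"""Readers, writers, fixtures and run manifests.

Formats
-------
* **State file** (YAML): one document holding the model parameters, the
  discrete lattice state (protofilament/axial location, nucleotide and
  seam zip count) and the conformation (positions, velocities, masses,
  axis frame).  Round-trips losslessly; used for restart.
* **Extended XYZ**: one atom per monomer with columns
  ``element x y z protofilament axial kind nucleotide [energy]``; the
  element tag encodes kind and nucleotide state (C/N for GTP/GDP alpha,
  O/S for GTP/GDP beta) so ordinary viewers color the lattice sensibly.
  Multi-frame trajectories append.
* **PDB** (via biotite): one atom per monomer, one chain per
  protofilament, residue number = axial index + 1.
* **Event log**: one JSON object per line (:class:`mtsheet.events.EventRecord`).
* **Run manifest** (YAML): full configuration + seed + package version,
  sufficient to reproduce every output of a deterministic preset.
"""

from __future__ import annotations

import numpy as np
import yaml

from .events import EventRecord
from .lattice import (GDP, GTP, Conformation, Lattice, build_microtubule)
from .params import ModelParams, params_from_dict, _DERIVED_FIELDS

_ELEMENT = {("alpha", GTP): "C", ("alpha", GDP): "N",
            ("beta", GTP): "O", ("beta", GDP): "S"}


# ---------------------------------------------------------------------------
# state serialization
# ---------------------------------------------------------------------------

def save_state(path, lat: Lattice, conf: Conformation,
               params: ModelParams) -> None:
    """Write a lattice + conformation + parameters restart file (YAML)."""
    data = {
        "params": {k: v for k, v in params.to_dict().items()
                   if k not in _DERIVED_FIELDS},
        "lattice": {
            "n_protofilaments": lat.n_pf,
            "pitch_monomers": lat.pitch,
            "wrap_seam": lat.wrap_seam,
            "zipped_count": lat.zipped_count,
            "monomers": [[int(p), int(j), int(lat.nucleotide[g])]
                         for g, (p, j) in enumerate(lat._loc)],
        },
        "conformation": {
            "positions": np.asarray(conf.positions).tolist(),
            "velocities": np.asarray(conf.velocities).tolist(),
            "masses": np.asarray(conf.masses).tolist(),
            "axis_origin": np.asarray(conf.axis_origin).tolist(),
            "axis_direction": np.asarray(conf.axis_direction).tolist(),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_state(path) -> tuple[Lattice, Conformation, ModelParams]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    params = params_from_dict(data["params"])
    ld = data["lattice"]
    lat = Lattice(ld["n_protofilaments"], ld["pitch_monomers"],
                  ld["wrap_seam"])
    for p, j, nuc in ld["monomers"]:
        lat.add_monomer(p, j, nuc)
    lat.zipped_count = ld["zipped_count"]
    cd = data["conformation"]
    conf = Conformation(
        positions=np.asarray(cd["positions"], float),
        velocities=np.asarray(cd["velocities"], float),
        masses=np.asarray(cd["masses"], float),
        axis_origin=np.asarray(cd["axis_origin"], float),
        axis_direction=np.asarray(cd["axis_direction"], float),
    )
    conf.validate()
    return lat, conf, params


# ---------------------------------------------------------------------------
# trajectory writers
# ---------------------------------------------------------------------------

def write_xyz(path, lat: Lattice, conf: Conformation,
              energies: np.ndarray | None = None,
              comment: str = "", append: bool = False) -> None:
    """Write one extended-XYZ frame (optionally appending a trajectory)."""
    mode = "a" if append else "w"
    cols = "species:S:1:pos:R:3:proto:I:1:axial:I:1:kind:S:1:nucleotide:S:1"
    if energies is not None:
        cols += ":energy:R:1"
    with open(path, mode) as fh:
        fh.write(f"{lat.n_monomers}\n")
        fh.write(f'Properties={cols} Comment="{comment}"\n')
        for g in range(lat.n_monomers):
            p, j = lat.loc(g)
            kind = lat.kind(g)
            nuc = int(lat.nucleotide[g])
            el = _ELEMENT[(kind, nuc)]
            x, y, z = conf.positions[g]
            line = (f"{el} {x:.6f} {y:.6f} {z:.6f} {p} {j} "
                    f"{kind[0]} {'GTP' if nuc == GTP else 'GDP'}")
            if energies is not None:
                line += f" {energies[g]:.6e}"
            fh.write(line + "\n")


def read_xyz_frames(path) -> list[np.ndarray]:
    """Read back the position blocks of an (extended) XYZ trajectory."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(v) for v in parts[1:4]]
            frames.append(pos)
    return frames


def write_pdb(path, lat: Lattice, conf: Conformation) -> None:
    """Write the conformation as PDB: one atom per monomer, chain per
    protofilament, residue number = axial index + 1."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb
    n = lat.n_monomers
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(conf.positions, dtype=np.float32)
    chain_ids = []
    res_ids = np.zeros(n, dtype=int)
    names = []
    elements = []
    for g in range(n):
        p, j = lat.loc(g)
        chain_ids.append(chr(ord("A") + p % 26))
        res_ids[g] = j + 1
        kind = lat.kind(g)
        names.append("CA")
        elements.append(_ELEMENT[(kind, int(lat.nucleotide[g]))])
    atoms.chain_id = np.array(chain_ids)
    atoms.res_id = res_ids
    atoms.res_name = np.array(
        ["TBA" if lat.kind(g) == "alpha" else "TBB" for g in range(n)])
    atoms.atom_name = np.array(names)
    atoms.element = np.array(elements)
    atoms.hetero = np.full(n, True)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------

def write_event_log(path, events: list[EventRecord]) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_event_log(path) -> list[EventRecord]:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                events.append(EventRecord.from_json(line))
    return events


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def write_manifest(path, params: ModelParams, seed: int, preset: str,
                   extra: dict | None = None) -> None:
    from . import __version__
    data = {
        "preset": preset,
        "seed": int(seed),
        "version": __version__,
        "params": {k: v for k, v in params.to_dict().items()
                   if k not in _DERIVED_FIELDS},
    }
    if extra:
        data["extra"] = extra
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# deterministic RNG streams
# ---------------------------------------------------------------------------

#: substream indices per event class, so adding draws in one class can
#: never perturb another class's stream
_STREAMS = {"assembly": 0, "hydrolysis": 1, "misc": 2}


def rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent child generators per event class from one run seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(children[i])
            for name, i in _STREAMS.items()}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: ModelParams | None = None,
                 n_turns: int = 6) -> tuple[Lattice, Conformation]:
    """Small deterministic structures for oracle tests.

    ``planar_3x4``
        3 protofilaments x 4 monomers on a flat rectangular grid, no seam
        (hand-enumerable topology for brute-force energy oracles).
    ``tube_13xN``
        blunt closed tube of ``n_turns`` helical turns.
    ``sheet_standard``
        the standard experiment start: 10-turn body + 10-monomer GTP
        sheet (construction guess; relax before measuring).
    """
    if params is None:
        params = ModelParams()
    if kind == "planar_3x4":
        lat = Lattice(n_protofilaments=3, pitch_monomers=params.pitch_monomers,
                      wrap_seam=False)
        pos = []
        for p in range(3):
            for j in range(4):
                lat.add_monomer(p, j, GTP)
                pos.append([p * params.r0_lat, 0.0, j * params.r0_long])
        conf = Conformation(np.asarray(pos, float),
                            np.zeros((12, 3)), np.full(12, params.monomer_mass))
        return lat, conf
    if kind == "tube_13xN":
        return build_microtubule(params, n_turns * params.pitch_monomers, 0)
    if kind == "sheet_standard":
        return build_microtubule(params, 30, 10)
    raise ValueError(f"unknown fixture kind {kind!r}")
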