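"""The seven interaction potentials: energies, breakdowns, analytic forces.

Every interaction is a harmonic penalty ``E = k/2 * deviation^2`` on one
geometric deviation:

* stretch classes (longitudinal, lateral, diagonal): deviation of the
  pair distance from its rest length, k in nN/nm;
* bend classes (longitudinal, lateral): deviation of the supplementary
  angle of a bonded triple from its equilibrium value, k in nN*nm per
  radian^2.  The longitudinal equilibrium angle is nucleotide dependent
  (5 deg GTP, 18 deg GDP); the lateral one is zero (tubulin sheets are
  flat);
* dihedral classes (longitudinal, lateral): deviation of a twist angle
  measured against the local surface normal from zero.

Dihedral twist angles are measured between a molecular plane and a
reference plane built on a *radial direction*.  Two conventions are
implemented (``ModelParams.dihedral_reference``):

``tube_axis`` (default)
    radial directions point away from the microtubule axis stored on the
    conformation.  This is the model's own definition: the lattice
    remembers its tubular frame, which weakly resists unrolling of the
    open sheet.  The axis transforms with the conformation under rigid
    motions, so energies are frame invariant; within a fixed frame the
    axis acts as an external reference for the (small) dihedral terms.
``local_normal``
    radial directions are the local surface normals built from the
    lattice's own bonds (axial cross lateral neighbour).  Fully internal:
    forces obey Newton's third law term by term and net torque vanishes
    exactly, but a uniformly unrolling sheet feels no twist penalty.

The dihedral penalty is ``k/2 * sin^2(theta)`` with epsilon-regularised
denominators: identical to the harmonic ``k/2 theta^2`` to O(theta^4) and
smooth through the collinear degeneracy of straight protofilaments, where
the twist angle itself is undefined (see ``_kernels``).

Angular terms and their gradients are evaluated by generated closed-form
kernels (:mod:`mtsheet._kernels`), compiled with numba together with the
accumulation loops below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from numba import njit

from ._kernels import (bend_term, dih_lat_axis_term, dih_lat_term,
                       dih_long_axis_term, dih_long_term)
from .lattice import Lattice, Conformation, Topology, build_topology
from .params import ModelParams

_bend = njit(cache=True)(bend_term)
_dih_long = njit(cache=True)(dih_long_term)
_dih_lat = njit(cache=True)(dih_lat_term)
_dih_long_axis = njit(cache=True)(dih_long_axis_term)
_dih_lat_axis = njit(cache=True)(dih_lat_axis_term)


def harmonic_energy(k: float, deviation: float) -> float:
    """``k/2 * deviation^2`` — the common form of all seven potentials."""
    if k < 0:
        raise ValueError("spring constant must be >= 0")
    return 0.5 * k * deviation * deviation


# ---------------------------------------------------------------------------
# single-term geometry (API level; reuses the compiled kernels)
# ---------------------------------------------------------------------------

def bend_angle(a, b, c) -> float:
    """Supplement of the interior angle at ``b``: 0 for a straight chain."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    if np.allclose(a, b) or np.allclose(b, c):
        raise ValueError("degenerate bend: coincident points")
    return _bend(a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2],
                 0.0, 0.0)[0]


def longitudinal_dihedral_angle(a, b, c, ref, sign: float = 1.0) -> float:
    """Signed twist of the chain (a, b, c) out of its surface-normal plane.

    ``ref`` is the lateral reference neighbour of ``a``; ``sign`` is +1 when
    it is the counterclockwise neighbour, -1 otherwise.
    """
    a, b, c, ref = (np.asarray(x, float) for x in (a, b, c, ref))
    n1 = np.cross(ref - a, b - a)
    n2 = np.cross(b - a, c - b)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate dihedral: collinear triple")
    args = np.concatenate([a, b, c, ref])
    return _dih_long(*args, 0.0, sign)[0]


def lateral_dihedral_angle(d, e, f, up_d, up_e) -> float:
    """Signed angle between the tangent planes at the two lateral bonds.

    ``up_d`` and ``up_e`` are the axial neighbours of ``d`` and ``e`` that
    fix the local surface normals.  The sign follows the triple product of
    the two plane normals with the bond d->e (a mirror reflection negates
    it); the potential itself depends only on the magnitude.
    """
    d, e, f, up_d, up_e = (np.asarray(x, float) for x in (d, e, f, up_d, up_e))
    nd = np.cross(e - d, up_d - d)
    ne = np.cross(f - e, up_e - e)
    if np.linalg.norm(nd) < 1e-9 or np.linalg.norm(ne) < 1e-9:
        raise ValueError("degenerate lateral dihedral: collinear triple")
    m1 = np.cross(nd / np.linalg.norm(nd), e - d)
    m2 = np.cross(ne / np.linalg.norm(ne), f - e)
    args = np.concatenate([d, e, f, up_d, up_e])
    theta = _dih_lat(*args, 0.0)[0]
    s = float(np.dot(np.cross(m1, m2), (e - d) / np.linalg.norm(e - d)))
    return math.copysign(theta, s) if s != 0.0 else theta


def longitudinal_dihedral_angle_axis(a, b, c, origin=(0.0, 0.0, 0.0),
                                     direction=(0.0, 0.0, 1.0)) -> float:
    """Signed twist of (a, b, c) against the tube-axis radial reference."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    o = np.asarray(origin, float)
    u = np.asarray(direction, float)
    return _dih_long_axis(*a, *b, *c, *o, *u, 0.0)[0]


def lateral_dihedral_angle_axis(d, e, f, origin=(0.0, 0.0, 0.0),
                                direction=(0.0, 0.0, 1.0)) -> float:
    """Signed plane-plane angle of a turn triple, tube-axis references."""
    d, e, f = (np.asarray(x, float) for x in (d, e, f))
    o = np.asarray(origin, float)
    u = np.asarray(direction, float)
    theta = _dih_lat_axis(*d, *e, *f, *o, *u, 0.0)[0]

    def radial(x):
        w = x - o
        wp = w - np.dot(w, u) * u
        return wp / np.linalg.norm(wp)

    m1 = np.cross(radial(d), e - d)
    m2 = np.cross(radial(e), f - e)
    s = float(np.dot(np.cross(m1, m2), (e - d) / np.linalg.norm(e - d)))
    return math.copysign(theta, s) if s != 0.0 else theta


# ---------------------------------------------------------------------------
# numba accumulation loops
# ---------------------------------------------------------------------------

@njit(cache=True)
def _accum_stretch(pos, pairs, kk, r0, forces, per_mono):
    e = 0.0
    for t in range(pairs.shape[0]):
        i = pairs[t, 0]
        j = pairs[t, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        dev = d - r0[t]
        et = 0.5 * kk * dev * dev
        e += et
        if d > 0.0:
            f = -kk * dev / d
            fx = f * dx
            fy = f * dy
            fz = f * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
        per_mono[i] += 0.5 * et
        per_mono[j] += 0.5 * et
    return e


@njit(cache=True)
def _accum_bend(pos, triples, kk, t0, forces, per_mono):
    e = 0.0
    for t in range(triples.shape[0]):
        a = triples[t, 0]
        b = triples[t, 1]
        c = triples[t, 2]
        out = _bend(pos[a, 0], pos[a, 1], pos[a, 2],
                    pos[b, 0], pos[b, 1], pos[b, 2],
                    pos[c, 0], pos[c, 1], pos[c, 2], kk, t0[t])
        et = out[1]
        e += et
        forces[a, 0] -= out[2]
        forces[a, 1] -= out[3]
        forces[a, 2] -= out[4]
        forces[b, 0] -= out[5]
        forces[b, 1] -= out[6]
        forces[b, 2] -= out[7]
        forces[c, 0] -= out[8]
        forces[c, 1] -= out[9]
        forces[c, 2] -= out[10]
        third = et / 3.0
        per_mono[a] += third
        per_mono[b] += third
        per_mono[c] += third
    return e


@njit(cache=True)
def _accum_dih_long(pos, quads, sgn, kk, forces, per_mono):
    e = 0.0
    for t in range(quads.shape[0]):
        a = quads[t, 0]
        b = quads[t, 1]
        c = quads[t, 2]
        l = quads[t, 3]
        out = _dih_long(pos[a, 0], pos[a, 1], pos[a, 2],
                        pos[b, 0], pos[b, 1], pos[b, 2],
                        pos[c, 0], pos[c, 1], pos[c, 2],
                        pos[l, 0], pos[l, 1], pos[l, 2], kk, sgn[t])
        et = out[1]
        e += et
        forces[a, 0] -= out[2]
        forces[a, 1] -= out[3]
        forces[a, 2] -= out[4]
        forces[b, 0] -= out[5]
        forces[b, 1] -= out[6]
        forces[b, 2] -= out[7]
        forces[c, 0] -= out[8]
        forces[c, 1] -= out[9]
        forces[c, 2] -= out[10]
        forces[l, 0] -= out[11]
        forces[l, 1] -= out[12]
        forces[l, 2] -= out[13]
        q = et / 4.0
        per_mono[a] += q
        per_mono[b] += q
        per_mono[c] += q
        per_mono[l] += q
    return e


@njit(cache=True)
def _accum_dih_long_axis(pos, quads, origin, axis, kk, forces, per_mono):
    e = 0.0
    ox, oy, oz = origin[0], origin[1], origin[2]
    ux, uy, uz = axis[0], axis[1], axis[2]
    for t in range(quads.shape[0]):
        a = quads[t, 0]
        b = quads[t, 1]
        c = quads[t, 2]
        out = _dih_long_axis(pos[a, 0], pos[a, 1], pos[a, 2],
                             pos[b, 0], pos[b, 1], pos[b, 2],
                             pos[c, 0], pos[c, 1], pos[c, 2],
                             ox, oy, oz, ux, uy, uz, kk)
        et = out[1]
        e += et
        forces[a, 0] -= out[2]
        forces[a, 1] -= out[3]
        forces[a, 2] -= out[4]
        forces[b, 0] -= out[5]
        forces[b, 1] -= out[6]
        forces[b, 2] -= out[7]
        forces[c, 0] -= out[8]
        forces[c, 1] -= out[9]
        forces[c, 2] -= out[10]
        third = et / 3.0
        per_mono[a] += third
        per_mono[b] += third
        per_mono[c] += third
    return e


@njit(cache=True)
def _accum_dih_lat_axis(pos, triples, origin, axis, kk, forces, per_mono):
    e = 0.0
    ox, oy, oz = origin[0], origin[1], origin[2]
    ux, uy, uz = axis[0], axis[1], axis[2]
    for t in range(triples.shape[0]):
        d = triples[t, 0]
        ee = triples[t, 1]
        f = triples[t, 2]
        out = _dih_lat_axis(pos[d, 0], pos[d, 1], pos[d, 2],
                            pos[ee, 0], pos[ee, 1], pos[ee, 2],
                            pos[f, 0], pos[f, 1], pos[f, 2],
                            ox, oy, oz, ux, uy, uz, kk)
        et = out[1]
        e += et
        forces[d, 0] -= out[2]
        forces[d, 1] -= out[3]
        forces[d, 2] -= out[4]
        forces[ee, 0] -= out[5]
        forces[ee, 1] -= out[6]
        forces[ee, 2] -= out[7]
        forces[f, 0] -= out[8]
        forces[f, 1] -= out[9]
        forces[f, 2] -= out[10]
        third = et / 3.0
        per_mono[d] += third
        per_mono[ee] += third
        per_mono[f] += third
    return e


@njit(cache=True)
def _accum_dih_lat(pos, quints, kk, forces, per_mono):
    e = 0.0
    for t in range(quints.shape[0]):
        d = quints[t, 0]
        ee = quints[t, 1]
        f = quints[t, 2]
        p = quints[t, 3]
        q = quints[t, 4]
        out = _dih_lat(pos[d, 0], pos[d, 1], pos[d, 2],
                       pos[ee, 0], pos[ee, 1], pos[ee, 2],
                       pos[f, 0], pos[f, 1], pos[f, 2],
                       pos[p, 0], pos[p, 1], pos[p, 2],
                       pos[q, 0], pos[q, 1], pos[q, 2], kk)
        et = out[1]
        e += et
        forces[d, 0] -= out[2]
        forces[d, 1] -= out[3]
        forces[d, 2] -= out[4]
        forces[ee, 0] -= out[5]
        forces[ee, 1] -= out[6]
        forces[ee, 2] -= out[7]
        forces[f, 0] -= out[8]
        forces[f, 1] -= out[9]
        forces[f, 2] -= out[10]
        forces[p, 0] -= out[11]
        forces[p, 1] -= out[12]
        forces[p, 2] -= out[13]
        forces[q, 0] -= out[14]
        forces[q, 1] -= out[15]
        forces[q, 2] -= out[16]
        fifth = et / 5.0
        per_mono[d] += fifth
        per_mono[ee] += fifth
        per_mono[f] += fifth
        per_mono[p] += fifth
        per_mono[q] += fifth
    return e


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    """The seven interaction-energy components and their total (nN*nm)."""

    e_long_stretch: float
    e_lat_stretch: float
    e_diag_stretch: float
    e_long_bend: float
    e_lat_bend: float
    e_long_dihedral: float
    e_lat_dihedral: float
    e_total: float

    COMPONENTS = ("e_long_stretch", "e_lat_stretch", "e_diag_stretch",
                  "e_long_bend", "e_lat_bend", "e_long_dihedral",
                  "e_lat_dihedral")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class EnergyModel:
    """Precompiled evaluator of energies and forces for one topology.

    Rebuild (cheap) whenever the lattice state changes: the constructor
    freezes the index arrays, per-term constants and equilibrium angles.
    """

    def __init__(self, lat: Lattice, params: ModelParams,
                 topology: Topology | None = None):
        self.lattice = lat
        self.params = params
        self.topology = topology if topology is not None else build_topology(lat, params)
        t = self.topology
        self._r0_long = np.full(len(t.stretch_long), params.r0_long)
        self._r0_lat = np.full(len(t.stretch_lat), params.lateral_rest_length)
        self._theta0_lat = np.full(len(t.bend_lat), math.radians(params.theta0_lat))

    def compute(self, conf_or_pos, with_forces: bool = True,
                per_monomer: bool = False):
        """Evaluate the energy breakdown (and optionally forces).

        Returns ``(EnergyBreakdown, forces, per_monomer_energy)``; the last
        two are None when not requested.
        """
        if isinstance(conf_or_pos, Conformation):
            pos = conf_or_pos.positions
            axis_origin = conf_or_pos.axis_origin
            axis_dir = conf_or_pos.axis_direction
        else:
            pos = np.asarray(conf_or_pos, float)
            axis_origin = np.zeros(3)
            axis_dir = np.array([0.0, 0.0, 1.0])
        n = pos.shape[0]
        t = self.topology
        p = self.params
        forces = np.zeros((n, 3))
        pm = np.zeros(n)
        e_ls = _accum_stretch(pos, t.stretch_long, p.k_long_stretch,
                              self._r0_long, forces, pm)
        e_as = _accum_stretch(pos, t.stretch_lat, p.k_lat_stretch,
                              self._r0_lat, forces, pm)
        e_ds = _accum_stretch(pos, t.stretch_diag, p.k_diag_stretch,
                              t.stretch_diag_r0, forces, pm)
        e_lb = _accum_bend(pos, t.bend_long, p.k_long_bend,
                           t.bend_long_theta0, forces, pm)
        e_ab = _accum_bend(pos, t.bend_lat, p.k_lat_bend,
                           self._theta0_lat, forces, pm)
        if p.dihedral_reference == "tube_axis":
            # axis-referenced twist terms exist wherever bend terms do
            e_ld = _accum_dih_long_axis(pos, t.bend_long, axis_origin,
                                        axis_dir, p.k_long_dihedral,
                                        forces, pm)
            e_ad = _accum_dih_lat_axis(pos, t.bend_lat, axis_origin,
                                       axis_dir, p.k_lat_dihedral,
                                       forces, pm)
        else:
            e_ld = _accum_dih_long(pos, t.dih_long, t.dih_long_sign,
                                   p.k_long_dihedral, forces, pm)
            e_ad = _accum_dih_lat(pos, t.dih_lat, p.k_lat_dihedral,
                                  forces, pm)
        total = e_ls + e_as + e_ds + e_lb + e_ab + e_ld + e_ad
        breakdown = EnergyBreakdown(e_ls, e_as, e_ds, e_lb, e_ab, e_ld,
                                    e_ad, total)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite interaction energy")
        return (breakdown,
                forces if with_forces else None,
                pm if per_monomer else None)

    def energy(self, conf_or_pos) -> float:
        return self.compute(conf_or_pos, with_forces=False)[0].e_total


def total_energy(lat: Lattice, conf: Conformation, params: ModelParams,
                 per_monomer: bool = False):
    """Energy breakdown of one conformation (convenience wrapper).

    Returns ``EnergyBreakdown`` or ``(EnergyBreakdown, per_monomer_array)``.
    """
    model = EnergyModel(lat, params)
    breakdown, _, pm = model.compute(conf, with_forces=False,
                                     per_monomer=per_monomer)
    return (breakdown, pm) if per_monomer else breakdown


def forces(lat: Lattice, conf: Conformation, params: ModelParams) -> np.ndarray:
    """Analytic forces, nN: the negative gradient of the total energy."""
    model = EnergyModel(lat, params)
    return model.compute(conf)[1]
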