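"""Independent brute-force energy oracle for the interaction model.

Re-implements the documented term definitions directly in numpy, term by
term, without touching the generated kernels or the numba accumulators.
Used to cross-check :class:`mtsheet.energetics.EnergyModel` on small
fixtures.
"""

import math

import numpy as np

EPS = 1e-12     # normalisation regulariser (nm^2 scale)
EPSD = 1e-2     # sin^2 dihedral denominator regulariser (nm^4 scale)


def stretch_energy(pos, pairs, k, r0):
    e = 0.0
    r0 = np.broadcast_to(np.asarray(r0, float), (len(pairs),))
    for (i, j), rest in zip(pairs, r0):
        d = np.linalg.norm(pos[i] - pos[j])
        e += 0.5 * k * (d - rest) ** 2
    return e


def bend_energy(pos, triples, k, theta0):
    e = 0.0
    theta0 = np.broadcast_to(np.asarray(theta0, float), (len(triples),))
    for (a, b, c), t0 in zip(triples, theta0):
        u = pos[a] - pos[b]
        v = pos[c] - pos[b]
        theta = math.atan2(math.sqrt(np.dot(np.cross(u, v), np.cross(u, v))
                                     + EPS), -np.dot(u, v))
        e += 0.5 * k * (theta - t0) ** 2
    return e


def _sin2(n1, n2):
    cr = np.cross(n1, n2)
    return np.dot(cr, cr) / ((np.dot(n1, n1) + EPSD)
                             * (np.dot(n2, n2) + EPSD))


def _radial(x, origin, direction):
    w = np.asarray(x, float) - origin
    wp = w - np.dot(w, direction) * direction
    return wp / math.sqrt(np.dot(wp, wp) + EPS)


def dih_long_axis_energy(pos, triples, k, origin, direction):
    e = 0.0
    for a, b, c in triples:
        b1 = -_radial(pos[a], origin, direction)
        b2 = pos[b] - pos[a]
        b3 = pos[c] - pos[b]
        e += 0.5 * k * _sin2(np.cross(b1, b2), np.cross(b2, b3))
    return e


def dih_lat_axis_energy(pos, triples, k, origin, direction):
    e = 0.0
    for d, ee, f in triples:
        m1 = np.cross(_radial(pos[d], origin, direction), pos[ee] - pos[d])
        m2 = np.cross(_radial(pos[ee], origin, direction), pos[f] - pos[ee])
        e += 0.5 * k * _sin2(m1, m2)
    return e


def dih_long_local_energy(pos, quads, signs, k):
    e = 0.0
    for (a, b, c, l), sgn in zip(quads, signs):
        n = np.cross(pos[l] - pos[a], pos[b] - pos[a])
        n = sgn * n / math.sqrt(np.dot(n, n) + EPS)
        b2 = pos[b] - pos[a]
        e += 0.5 * k * _sin2(np.cross(-n, b2), np.cross(b2, pos[c] - pos[b]))
    return e


def dih_lat_local_energy(pos, quints, k):
    e = 0.0
    for d, ee, f, p, q in quints:
        nd = np.cross(pos[ee] - pos[d], pos[p] - pos[d])
        ne = np.cross(pos[f] - pos[ee], pos[q] - pos[ee])
        m1 = np.cross(nd, pos[ee] - pos[d])
        m2 = np.cross(ne, pos[f] - pos[ee])
        e += 0.5 * k * _sin2(m1, m2)
    return e


def total_energy_oracle(lat, conf, params, topology):
    """Seven-component brute-force energy, same term enumeration."""
    pos = np.asarray(conf.positions, float)
    t = topology
    p = params
    origin = np.asarray(conf.axis_origin, float)
    direction = np.asarray(conf.axis_direction, float)
    comps = {
        "e_long_stretch": stretch_energy(pos, t.stretch_long,
                                         p.k_long_stretch, p.r0_long),
        "e_lat_stretch": stretch_energy(pos, t.stretch_lat, p.k_lat_stretch,
                                        p.lateral_rest_length),
        "e_diag_stretch": stretch_energy(pos, t.stretch_diag,
                                         p.k_diag_stretch, t.stretch_diag_r0),
        "e_long_bend": bend_energy(pos, t.bend_long, p.k_long_bend,
                                   t.bend_long_theta0),
        "e_lat_bend": bend_energy(pos, t.bend_lat, p.k_lat_bend,
                                  math.radians(p.theta0_lat)),
    }
    if p.dihedral_reference == "tube_axis":
        comps["e_long_dihedral"] = dih_long_axis_energy(
            pos, t.bend_long, p.k_long_dihedral, origin, direction)
        comps["e_lat_dihedral"] = dih_lat_axis_energy(
            pos, t.bend_lat, p.k_lat_dihedral, origin, direction)
    else:
        comps["e_long_dihedral"] = dih_long_local_energy(
            pos, t.dih_long, t.dih_long_sign, p.k_long_dihedral)
        comps["e_lat_dihedral"] = dih_lat_local_energy(
            pos, t.dih_lat, p.k_lat_dihedral)
    comps["e_total"] = sum(comps.values())
    return comps
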