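"""Generate closed-form energy/gradient kernels for the angular interactions.

The bend and dihedral potentials need exact analytic gradients (the force
tests compare against central finite differences at 1e-6 relative).  Rather
than hand-deriving the chain rule through the normalisations and atan2
calls, the expressions are built symbolically here and emitted as plain
scalar Python functions, which ``mtsheet.energetics`` compiles with numba.

Run from the repository root::

    python tools/generate_kernels.py

which rewrites ``src/mtsheet/_kernels.py``.  The generated module is
committed, so sympy is a development-time dependency only.
"""

from __future__ import annotations

import pathlib
import textwrap

import sympy as sp
from sympy.printing.pycode import pycode

EPS = sp.Float(1e-12)
#: additive bias on the cosine argument of atan2 (reported angles only):
#: keeps the angle defined at exactly degenerate geometries.
EPSC = sp.Float(1e-9)
#: regulariser (nm^4) of the sin^2 dihedral penalty denominators.  The
#: twist angle between two planes is undefined when either defining normal
#: vanishes (a collinear chain -- which genuinely occurs: protofilaments
#: held straight inside the tube).  Penalising sin^2(theta) with
#: |n|^2 + EPSD in the denominators makes the energy and its gradient
#: smooth and bounded through the degeneracy while matching the harmonic
#: theta^2 penalty to O(theta^4) where the angle is well defined.
EPSD = sp.Float(1e-2)


def vec(name: str) -> sp.Matrix:
    return sp.Matrix(sp.symbols(f"{name}x {name}y {name}z", real=True))


def unit(v: sp.Matrix) -> sp.Matrix:
    return v / sp.sqrt(v.dot(v) + EPS)


def sin2_between(n1: sp.Matrix, n2: sp.Matrix):
    cr = n1.cross(n2)
    return cr.dot(cr) / ((n1.dot(n1) + EPSD) * (n2.dot(n2) + EPSD))


def bend_exprs():
    """Bend term on a triple (A, B, C).

    The angle is the supplement of the interior angle at B, i.e. the
    deflection of the chain from straight: theta = atan2(|u x v|, -u.v)
    with u = A - B, v = C - B.  Energy is kk/2 (theta - t0)^2.
    """
    A, B, C = vec("a"), vec("b"), vec("c")
    kk, t0 = sp.symbols("kk t0", real=True)
    u = A - B
    v = C - B
    cr = u.cross(v)
    theta = sp.atan2(sp.sqrt(cr.dot(cr) + EPS), -u.dot(v))
    e = kk / 2 * (theta - t0) ** 2
    coords = list(A) + list(B) + list(C)
    grads = [sp.diff(e, q) for q in coords]
    args = [str(s) for s in coords + [kk, t0]]
    return args, [theta, e] + grads


def dih_long_exprs():
    """Longitudinal dihedral on (A, B, C) with lateral reference neighbour L.

    The local surface normal at A is n = unit(sgn * (L - A) x (B - A)); a
    virtual point A' = A + n supplies the reference half-plane.  The signed
    angle is the standard four-point dihedral of (A', A, B, C) about the
    bond A-B: zero when the chain bends within the local surface-normal
    plane (radially, on the tube), +/-pi/2 for pure sideways bending.
    ``sgn`` is +1 when L is the counterclockwise neighbour and -1 for the
    clockwise fallback so that both choices measure the same twist.
    The energy penalises kk/2 * sin^2(theta) (equal to the harmonic
    kk/2 theta^2 to O(theta^4)), which is smooth and bounded through the
    collinear degeneracy where the twist angle itself is undefined.
    """
    A, B, C, L = vec("a"), vec("b"), vec("c"), vec("l")
    kk, sgn = sp.symbols("kk sgn", real=True)
    n = unit((L - A).cross(B - A)) * sgn
    b1 = -n                      # A - A'
    b2 = B - A
    b3 = C - B
    n1 = b1.cross(b2)
    n2 = b2.cross(b3)
    b2h = unit(b2)
    theta = sp.atan2(n1.cross(n2).dot(b2h), n1.dot(n2) + EPSC)
    e = kk / 2 * sin2_between(n1, n2)
    coords = list(A) + list(B) + list(C) + list(L)
    grads = [sp.diff(e, q) for q in coords]
    args = [str(s) for s in coords + [kk, sgn]]
    return args, [theta, e] + grads


def dih_lat_exprs():
    """Lateral dihedral on a helical-turn triple (D, E, F).

    P and Q are the longitudinal (upward) neighbours of D and E; the local
    surface normals n_D = unit((E - D) x (P - D)) and n_E analogous define
    the planes (D', D, E) and (E', E, F) through virtual points D' = D + n_D
    and E' = E + n_E.  The term returns the unsigned angle between the two
    plane normals (the API layer restores the sign from the triple
    product) and penalises kk/2 * sin^2 of it, matching the harmonic form
    for small angles while staying smooth at degeneracies.
    """
    D, E, F, P, Q = vec("d"), vec("e"), vec("f"), vec("p"), vec("q")
    kk = sp.symbols("kk", real=True)
    nD = (E - D).cross(P - D)
    nE = (F - E).cross(Q - E)
    m1 = nD.cross(E - D)
    m2 = nE.cross(F - E)
    cr = m1.cross(m2)
    theta = sp.atan2(sp.sqrt(cr.dot(cr) + EPS), m1.dot(m2) + EPSC)
    e = kk / 2 * sin2_between(m1, m2)
    coords = list(D) + list(E) + list(F) + list(P) + list(Q)
    grads = [sp.diff(e, q) for q in coords]
    args = [str(s) for s in coords + [kk]]
    return args, [theta, e] + grads


def radial(X: sp.Matrix, O: sp.Matrix, U: sp.Matrix) -> sp.Matrix:
    """Unit radial direction of point X from the axis (origin O, unit dir U)."""
    w = X - O
    wp = w - w.dot(U) * U
    return wp / sp.sqrt(wp.dot(wp) + EPS)


def axis_syms():
    return vec("o"), vec("u")


def dih_long_axis_exprs():
    """Longitudinal dihedral for (A, B, C) with tube-axis radial reference.

    The reference half-plane through A' = A + r(A) uses the radial
    direction of A from the microtubule axis; otherwise identical to the
    local-normal variant (sin^2 penalty, signed angle about the bond A-B).
    Gradients are taken with respect to the monomer coordinates; the axis
    is a fixed frame of the conformation.
    """
    A, B, C = vec("a"), vec("b"), vec("c")
    O, U = axis_syms()
    kk = sp.symbols("kk", real=True)
    b1 = -radial(A, O, U)
    b2 = B - A
    b3 = C - B
    n1 = b1.cross(b2)
    n2 = b2.cross(b3)
    theta = sp.atan2(n1.cross(n2).dot(unit(b2)), n1.dot(n2) + EPSC)
    e = kk / 2 * sin2_between(n1, n2)
    coords = list(A) + list(B) + list(C)
    grads = [sp.diff(e, q) for q in coords]
    args = [str(s) for s in coords + list(O) + list(U) + [kk]]
    return args, [theta, e] + grads


def dih_lat_axis_exprs():
    """Lateral dihedral for (D, E, F) with tube-axis radial references.

    Plane normals m1 = r(D) x (E - D) and m2 = r(E) x (F - E) with radial
    directions taken from the microtubule axis; sin^2 penalty of the angle
    between them.
    """
    D, E, F = vec("d"), vec("e"), vec("f")
    O, U = axis_syms()
    kk = sp.symbols("kk", real=True)
    m1 = radial(D, O, U).cross(E - D)
    m2 = radial(E, O, U).cross(F - E)
    cr = m1.cross(m2)
    theta = sp.atan2(sp.sqrt(cr.dot(cr) + EPS), m1.dot(m2) + EPSC)
    e = kk / 2 * sin2_between(m1, m2)
    coords = list(D) + list(E) + list(F)
    grads = [sp.diff(e, q) for q in coords]
    args = [str(s) for s in coords + list(O) + list(U) + [kk]]
    return args, [theta, e] + grads


def emit(name: str, args: list[str], outputs, doc: str) -> str:
    reps, reduced = sp.cse(outputs, symbols=sp.numbered_symbols("t"),
                           optimizations="basic")
    lines = [f"def {name}({', '.join(args)}):"]
    lines.append(f'    """{doc}"""')
    for sym, expr in reps:
        lines.append(f"    {sym} = {pycode(expr)}")
    ret = ",\n            ".join(pycode(e) for e in reduced)
    lines.append(f"    return ({ret})")
    return "\n".join(lines)


HEADER = '''\
"""Scalar energy/gradient kernels for the angular interaction terms.

GENERATED by tools/generate_kernels.py -- do not edit by hand.

Each function returns ``(angle, energy, dE/dq...)`` for one interaction
term, with one gradient component per input coordinate in argument order.
A small epsilon (1e-12) regularises every normalisation so degenerate
(collinear) geometries give damped, finite gradients instead of NaNs.
"""

import math

__all__ = ["bend_term", "dih_long_term", "dih_lat_term",
           "dih_long_axis_term", "dih_lat_axis_term"]

'''


def main() -> None:
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "mtsheet" / "_kernels.py"
    parts = [HEADER]
    for name, builder, doc in [
        ("bend_term", bend_exprs,
         "Supplementary bend angle at B for (A, B, C); E = kk/2 (theta-t0)^2."),
        ("dih_long_term", dih_long_exprs,
         "Signed longitudinal dihedral for (A, B, C) with lateral reference L."),
        ("dih_lat_term", dih_lat_exprs,
         "Unsigned lateral dihedral for turn triple (D, E, F); P, Q are the "
         "axial neighbours of D and E."),
        ("dih_long_axis_term", dih_long_axis_exprs,
         "Signed longitudinal dihedral for (A, B, C), radial reference from "
         "the tube axis (origin o, unit direction u)."),
        ("dih_lat_axis_term", dih_lat_axis_exprs,
         "Unsigned lateral dihedral for (D, E, F), radial references from "
         "the tube axis (origin o, unit direction u)."),
    ]:
        args, outputs = builder()
        parts.append(emit(name, args, outputs, doc))
        parts.append("")
    out.write_text("\n\n".join(parts))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
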