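"""Microtubule lattice construction and interaction topology.

The lattice is the canonical B-type microtubule: ``n`` protofilaments
(default 13) of coarse-grained monomers (one particle per tubulin monomer,
two per dimer) arranged on a cylinder with a ``pitch``-monomer helical
offset (default 3).  Because the lateral helix rises by
``pitch * r0_long / n`` per step, wrapping around the tube leaves a seam
between the last and the first protofilament whose lateral contacts join
monomer ``(n-1, j)`` to monomer ``(0, j + pitch)``.

The growing plus end is an open sheet: above the zip front the seam carries
no lateral interactions, so the lattice there is a helical ribbon that is
free to flatten and flare outward.  Closure events zip the seam one monomer
pair at a time (see :mod:`mtsheet.events`).

Monomer kinds alternate along a protofilament (alpha at even axial index,
beta above it).  Nucleotide state is stored per monomer: hydrolysis of a
tubulin switches the equilibrium longitudinal bend angle of the interfaces
it controls from the GTP to the GDP value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, derive_geometry

GTP = 0
GDP = 1

ALPHA = "alpha"
BETA = "beta"


class FullyZippedError(RuntimeError):
    """Raised when a closure is requested on a blunt (fully zipped) tube."""


@dataclass(frozen=True)
class MonomerID:
    """Identity of one coarse-grained monomer."""

    protofilament_index: int
    axial_index: int
    kind: str            # ALPHA or BETA
    nucleotide: int      # GTP or GDP


def _default_origin() -> np.ndarray:
    return np.zeros(3)


def _default_axis() -> np.ndarray:
    return np.array([0.0, 0.0, 1.0])


@dataclass
class Conformation:
    """Positions, velocities and masses of all monomers (nm, nm/time, kDa).

    The conformation also carries the microtubule axis (origin + unit
    direction, default the lab z-axis through the origin): the dihedral
    interactions reference radial directions from this axis, and it
    transforms together with the positions under rigid motions.
    """

    positions: np.ndarray   # (N, 3)
    velocities: np.ndarray  # (N, 3)
    masses: np.ndarray      # (N,)
    axis_origin: np.ndarray = field(default_factory=_default_origin)
    axis_direction: np.ndarray = field(default_factory=_default_axis)

    def copy(self) -> "Conformation":
        return Conformation(self.positions.copy(), self.velocities.copy(),
                            self.masses.copy(), self.axis_origin.copy(),
                            self.axis_direction.copy())

    def transform(self, rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None) -> "Conformation":
        """Rigidly transform positions *and* the axis frame (new object)."""
        new = self.copy()
        if rotation is not None:
            rot = np.asarray(rotation, float)
            new.positions = new.positions @ rot.T
            new.velocities = new.velocities @ rot.T
            new.axis_origin = rot @ new.axis_origin
            new.axis_direction = rot @ new.axis_direction
        if translation is not None:
            new.positions = new.positions + translation
            new.axis_origin = new.axis_origin + translation
        return new

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocity array shape mismatch")
        if self.masses.shape[0] != self.positions.shape[0]:
            raise ValueError("mass array length mismatch")


class Lattice:
    """Monomer bookkeeping plus the derived interaction topology.

    Parameters
    ----------
    n_protofilaments, pitch_monomers:
        Lattice indices; the seam maps ``(n-1, j)`` to ``(0, j + pitch)``.
    wrap_seam:
        If False the lattice is a flat ribbon with no seam contacts at all
        (used by small planar test fixtures).
    """

    def __init__(self, n_protofilaments: int = 13, pitch_monomers: int = 3,
                 wrap_seam: bool = True):
        self.n_pf = n_protofilaments
        self.pitch = pitch_monomers
        self.wrap_seam = wrap_seam
        self._gid: dict[tuple[int, int], int] = {}
        self._loc: list[tuple[int, int]] = []
        self._pf_len = [0] * n_protofilaments
        self.nucleotide = np.zeros(0, dtype=np.uint8)
        self.zipped_count = 0

    # ------------------------------------------------------------------
    # bookkeeping
    # ------------------------------------------------------------------
    @property
    def n_monomers(self) -> int:
        return len(self._loc)

    def pf_len(self, p: int) -> int:
        return self._pf_len[p]

    @property
    def pf_lengths(self) -> list[int]:
        return list(self._pf_len)

    def gid(self, p: int, j: int) -> int | None:
        return self._gid.get((p, j))

    def loc(self, gid: int) -> tuple[int, int]:
        return self._loc[gid]

    def kind(self, gid: int) -> str:
        return ALPHA if self._loc[gid][1] % 2 == 0 else BETA

    def monomer(self, gid: int) -> MonomerID:
        p, j = self._loc[gid]
        return MonomerID(p, j, self.kind(gid), int(self.nucleotide[gid]))

    def monomers(self) -> list[MonomerID]:
        return [self.monomer(g) for g in range(self.n_monomers)]

    def add_monomer(self, p: int, j: int, nucleotide: int = GTP) -> int:
        if j != self._pf_len[p]:
            raise ValueError(
                f"monomer ({p}, {j}) must extend the tip (length {self._pf_len[p]})")
        gid = len(self._loc)
        self._gid[(p, j)] = gid
        self._loc.append((p, j))
        self._pf_len[p] = j + 1
        self.nucleotide = np.append(self.nucleotide, np.uint8(nucleotide))
        return gid

    # ------------------------------------------------------------------
    # seam state
    # ------------------------------------------------------------------
    def seam_pair(self, jp: int) -> tuple[int | None, int | None]:
        """Global ids of cross-seam pair ``jp``: ((n-1, jp), (0, jp+pitch))."""
        return self.gid(self.n_pf - 1, jp), self.gid(0, jp + self.pitch)

    def is_zipped(self, jp: int) -> bool:
        return self.wrap_seam and 0 <= jp < self.zipped_count

    def next_closure_pair(self) -> tuple[int, int, int]:
        """Return ``(jp, gid_left, gid_right)`` for the lowest unzipped pair.

        Raises :class:`FullyZippedError` when the seam is closed to the top
        (blunt end): the sheet has vanished and the growth regime is over.
        """
        if not self.wrap_seam:
            raise FullyZippedError("lattice has no seam")
        jp = self.zipped_count
        a, b = self.seam_pair(jp)
        if a is None or b is None:
            raise FullyZippedError("seam fully zipped: blunt microtubule end")
        return jp, a, b

    def zip_next_pair(self) -> tuple[int, int, int]:
        jp, a, b = self.next_closure_pair()
        self.zipped_count += 1
        return jp, a, b

    @property
    def zipped_height(self) -> int:
        return self.zipped_count

    @property
    def sheet_base_axial(self) -> int:
        """Axial index (on protofilament 0) where the open sheet begins."""
        return self.zipped_count + self.pitch

    # ------------------------------------------------------------------
    # neighbour helpers (bond-level: seam contacts only when zipped)
    # ------------------------------------------------------------------
    def lat_right(self, p: int, j: int) -> int | None:
        """Counterclockwise lateral neighbour of (p, j), or None."""
        if p < self.n_pf - 1:
            return self.gid(p + 1, j)
        if self.is_zipped(j):
            return self.gid(0, j + self.pitch)
        return None

    def lat_left(self, p: int, j: int) -> int | None:
        if p > 0:
            return self.gid(p - 1, j)
        if self.is_zipped(j - self.pitch):
            return self.gid(self.n_pf - 1, j - self.pitch)
        return None

    # ------------------------------------------------------------------
    def hydrolyze(self, gid: int) -> None:
        """GTP -> GDP; irreversible."""
        self.nucleotide[gid] = GDP

    def copy(self) -> "Lattice":
        new = Lattice(self.n_pf, self.pitch, self.wrap_seam)
        new._gid = dict(self._gid)
        new._loc = list(self._loc)
        new._pf_len = list(self._pf_len)
        new.nucleotide = self.nucleotide.copy()
        new.zipped_count = self.zipped_count
        return new

    def state_signature(self) -> tuple:
        """Hashable snapshot of the discrete lattice state (for rollback tests)."""
        return (tuple(self._loc), bytes(self.nucleotide.tobytes()),
                self.zipped_count)


# ---------------------------------------------------------------------------
# interaction topology
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Index arrays for the seven interaction classes.

    ``dih_long`` rows are ``(A, B, C, L)`` where L is the lateral reference
    neighbour of A and ``dih_long_sign`` is +1 when L is the
    counterclockwise neighbour, -1 for the clockwise fallback.  ``dih_lat``
    rows are ``(D, E, F, P, Q)`` with P, Q the axial (upward) neighbours of
    D and E.
    """

    stretch_long: np.ndarray     # (M, 2)
    stretch_lat: np.ndarray      # (M, 2)
    stretch_diag: np.ndarray     # (M, 2)
    stretch_diag_r0: np.ndarray  # (M,)
    bend_long: np.ndarray        # (M, 3)
    bend_long_theta0: np.ndarray  # (M,) radians
    bend_lat: np.ndarray         # (M, 3)
    dih_long: np.ndarray         # (M, 4)
    dih_long_sign: np.ndarray    # (M,)
    dih_lat: np.ndarray          # (M, 5)

    @property
    def n_terms(self) -> int:
        return (len(self.stretch_long) + len(self.stretch_lat)
                + len(self.stretch_diag) + len(self.bend_long)
                + len(self.bend_lat) + len(self.dih_long) + len(self.dih_lat))

    def term_counts(self) -> dict[str, int]:
        return {
            "stretch_long": len(self.stretch_long),
            "stretch_lat": len(self.stretch_lat),
            "stretch_diag": len(self.stretch_diag),
            "bend_long": len(self.bend_long),
            "bend_lat": len(self.bend_lat),
            "dih_long": len(self.dih_long),
            "dih_lat": len(self.dih_lat),
        }


def _as_array(rows: list, width: int) -> np.ndarray:
    if not rows:
        return np.zeros((0, width), dtype=np.int64)
    return np.asarray(rows, dtype=np.int64)


def build_topology(lat: Lattice, params: ModelParams) -> Topology:
    """Enumerate every interaction term implied by the lattice state.

    Terms are emitted in a deterministic order (protofilament-major, then
    axial), so identical lattice states always produce identical topology
    arrays.
    """
    if params.r0_diag_short is None:
        params = derive_geometry(params)
    n, pitch = lat.n_pf, lat.pitch

    s_long, s_lat, s_diag, diag_r0 = [], [], [], []
    b_long, b_long_t0, b_lat = [], [], []
    d_long, d_long_sgn, d_lat = [], [], []

    theta_gtp = params.theta0_long(False)
    theta_gdp = params.theta0_long(True)

    for p in range(n):
        L = lat.pf_len(p)
        for j in range(L):
            g = lat.gid(p, j)
            up = lat.gid(p, j + 1)
            # longitudinal stretch
            if up is not None:
                s_long.append((g, up))
            # longitudinal bend + dihedral, centred at (p, j)
            down = lat.gid(p, j - 1)
            if down is not None and up is not None:
                b_long.append((down, g, up))
                hyd = lat.nucleotide[g] == GDP
                b_long_t0.append(theta_gdp if hyd else theta_gtp)
                # lateral reference neighbour of the lower monomer A=(p, j-1)
                ref = lat.lat_right(p, j - 1)
                sgn = 1.0
                if ref is None:
                    ref = lat.lat_left(p, j - 1)
                    sgn = -1.0
                if ref is not None:
                    d_long.append((down, g, up, ref))
                    d_long_sgn.append(sgn)
            # lateral stretch to the counterclockwise neighbour
            right = lat.lat_right(p, j)
            if right is not None:
                s_lat.append((g, right))
            # diagonals (within the wall; seam diagonals optional)
            if p < n - 1:
                dl = lat.gid(p + 1, j + 1)
                if dl is not None:
                    s_diag.append((g, dl))
                    diag_r0.append(params.r0_diag_long)
                ds = lat.gid(p + 1, j - 1)
                if ds is not None:
                    s_diag.append((g, ds))
                    diag_r0.append(params.r0_diag_short)
            elif lat.wrap_seam and params.seam_diagonals:
                if lat.is_zipped(j) and lat.is_zipped(j + 1):
                    dl = lat.gid(0, j + pitch + 1)
                    if dl is not None:
                        s_diag.append((g, dl))
                        diag_r0.append(params.r0_diag_long)
                if lat.is_zipped(j) and lat.is_zipped(j - 1):
                    ds = lat.gid(0, j + pitch - 1)
                    if ds is not None:
                        s_diag.append((g, ds))
                        diag_r0.append(params.r0_diag_short)
            # lateral bend + dihedral centred at (p, j)
            left = lat.lat_left(p, j)
            if left is not None and right is not None:
                b_lat.append((left, g, right))
                pd, jd = lat.loc(left)
                up_d = lat.gid(pd, jd + 1)
                up_e = up
                if up_d is not None and up_e is not None:
                    d_lat.append((left, g, right, up_d, up_e))

    return Topology(
        stretch_long=_as_array(s_long, 2),
        stretch_lat=_as_array(s_lat, 2),
        stretch_diag=_as_array(s_diag, 2),
        stretch_diag_r0=np.asarray(diag_r0, dtype=np.float64),
        bend_long=_as_array(b_long, 3),
        bend_long_theta0=np.asarray(b_long_t0, dtype=np.float64),
        bend_lat=_as_array(b_lat, 3),
        dih_long=_as_array(d_long, 4),
        dih_long_sign=np.asarray(d_long_sgn, dtype=np.float64),
        dih_lat=_as_array(d_lat, 5),
    )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def tube_position(params: ModelParams, p: int, j: int) -> np.ndarray:
    """Reference position of monomer (p, j) on the closed cylinder."""
    r = params.cylinder_radius
    phi = 2.0 * math.pi * p / params.n_protofilaments
    z = j * params.r0_long + p * params.helical_rise
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


def build_lattice(params: ModelParams, n_closed_turns: int,
                  sheet_length_monomers: int,
                  sheet_nucleotide: int = GTP,
                  body_nucleotide: int = GDP,
                  ) -> tuple[Lattice, Conformation]:
    """Construct a sheet-ended microtubule and its initial conformation.

    The closed body spans ``n_closed_turns`` helical turns
    (``pitch_monomers`` monomers of rise each); above it every
    protofilament carries ``sheet_length_monomers`` additional monomers
    whose seam contacts are open.  See :func:`build_microtubule` for the
    details; this wrapper fixes the body length to whole helical turns.
    """
    if n_closed_turns < 1:
        raise ValueError("n_closed_turns must be >= 1")
    return build_microtubule(params,
                             n_closed_turns * params.pitch_monomers,
                             sheet_length_monomers,
                             sheet_nucleotide=sheet_nucleotide,
                             body_nucleotide=body_nucleotide)


def build_microtubule(params: ModelParams, body_monomers: int,
                      sheet_monomers: int,
                      sheet_nucleotide: int = GTP,
                      body_nucleotide: int = GDP,
                      ) -> tuple[Lattice, Conformation]:
    """Construct a sheet-ended microtubule with an arbitrary body length.

    Body monomers sit on the reference cylinder; sheet monomers start on
    an outward-flaring guess surface in which each protofilament bends
    radially outward by the GTP intrinsic angle per interface.  The guess
    is *not* an equilibrium: callers relax it (form-finding) before
    measuring energies.  By default the sheet is GTP and the body fully
    hydrolyzed (GDP).
    """
    if params.r0_diag_short is None:
        params = derive_geometry(params)
    if sheet_monomers < 0:
        raise ValueError("sheet_length_monomers must be >= 0")
    n = params.n_protofilaments
    pitch = params.pitch_monomers
    body_len = body_monomers
    if body_len < pitch + 1:
        raise ValueError("body must be at least pitch + 1 monomers tall")
    sheet_length_monomers = sheet_monomers
    total_len = body_len + sheet_length_monomers
    if sheet_length_monomers > total_len:
        raise ValueError("sheet longer than total protofilament length")

    lat = Lattice(n, pitch, wrap_seam=True)
    positions = np.zeros((n * total_len, 3))
    flare = math.radians(params.theta0_long_GTP)
    for p in range(n):
        # flare accumulators for the sheet part of this protofilament
        base = tube_position(params, p, body_len - 1)
        phi = 2.0 * math.pi * p / n
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        pos_prev = base
        for j in range(total_len):
            nuc = body_nucleotide if j < body_len else sheet_nucleotide
            gid = lat.add_monomer(p, j, nuc)
            if j < body_len:
                positions[gid] = tube_position(params, p, j)
            else:
                k = j - (body_len - 1)
                ang = k * flare
                step = params.r0_long * (math.cos(ang) * axial
                                         + math.sin(ang) * radial)
                pos_prev = pos_prev + step
                positions[gid] = pos_prev
    lat.zipped_count = max(body_len - pitch, 0)
    if sheet_length_monomers == 0:
        # blunt tube: zip every seam pair that exists
        lat.zipped_count = max(total_len - pitch, 0)

    conf = Conformation(
        positions=positions,
        velocities=np.zeros_like(positions),
        masses=np.full(n * total_len, params.monomer_mass),
    )
    return lat, conf


def conformation_from_lattice(lat: Lattice, params: ModelParams,
                              position_fn) -> Conformation:
    """Build a conformation by evaluating ``position_fn(p, j)`` per monomer."""
    pos = np.zeros((lat.n_monomers, 3))
    for gid in range(lat.n_monomers):
        p, j = lat.loc(gid)
        pos[gid] = position_fn(p, j)
    return Conformation(pos, np.zeros_like(pos),
                        np.full(lat.n_monomers, params.monomer_mass))
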