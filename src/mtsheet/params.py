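"""Model constants and derived lattice geometry.

All quantities are kept in the model's internal unit system: lengths in nm,
forces in nN, masses in kDa, energies in nN*nm.  One internal time unit is
sqrt(kDa * nm^2 / (nN*nm)); the Verlet step ``dt`` is expressed in these
units.  Thermal energies are converted through ``kBT_internal``
(4.141e-3 nN*nm per k_BT at 300 K).

The microtubule is the canonical 13-protofilament, 3-monomer-pitch lattice.
Because the lattice is oblique (each lateral step rises by
``pitch * r0_long / n_protofilaments``), the two diagonal neighbour
separations differ; :func:`derive_geometry` computes them from the cylinder
geometry together with the cylinder radius and helical rise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Boltzmann energy at 300 K in internal energy units (nN*nm).
KBT_300K = 4.141e-3

#: Intrinsic longitudinal bend per monomer interface, degrees.
THETA0_GTP_DEG = 5.0
THETA0_GDP_DEG = 18.0


@dataclass
class ModelParams:
    """Every physical constant and algorithm tolerance of the model.

    Spring constants for distance-type interactions are in nN/nm, for
    angle-type interactions in nN*nm per radian^2.  Equilibrium angles are
    stored in degrees (as usually quoted) and converted to radians at the
    energy-evaluation boundary.
    """

    # -- elastic constants ------------------------------------------------
    k_long_stretch: float = 3.0     # nN/nm
    k_lat_stretch: float = 14.0     # nN/nm
    k_diag_stretch: float = 3.0     # nN/nm
    k_long_bend: float = 2.0        # nN*nm
    k_lat_bend: float = 8.5         # nN*nm
    k_long_dihedral: float = 0.04   # nN*nm
    k_lat_dihedral: float = 0.17    # nN*nm

    # -- rest geometry ----------------------------------------------------
    r0_long: float = 4.0            # nm, longitudinal monomer interval
    r0_lat: float = 5.2             # nm, lateral monomer interval
    #: "nominal": the lateral stretch rest length is r0_lat applied to the
    #: Euclidean neighbour distance.  "chord": the rest length is the chord
    #: of one lateral step on the reference cylinder (r0_lat read as an arc
    #: length), which is the convention the diagonal rest lengths follow.
    lateral_rest_convention: str = "nominal"
    theta0_long_GTP: float = THETA0_GTP_DEG   # degrees
    theta0_long_GDP: float = THETA0_GDP_DEG   # degrees
    theta0_lat: float = 0.0                   # degrees
    phi0_long: float = 0.0                    # degrees (dihedral)
    phi0_lat: float = 0.0                     # degrees (dihedral)

    # -- association free energies, k_BT per dimer ------------------------
    dG_long: float = -19.0
    dG_lat: float = -4.0
    dG_S: float = 11.0

    # -- lattice ----------------------------------------------------------
    n_protofilaments: int = 13
    pitch_monomers: int = 3
    monomer_mass: float = 55.0      # kDa
    #: add diagonal terms across the seam when a pair is zipped
    seam_diagonals: bool = False
    #: reference frame of the dihedral (twist) interactions.
    #: "tube_axis": radial directions from the microtubule axis stored on
    #: the conformation (the model's definition; the lattice remembers the
    #: tubular frame, which resists unrolling of the open sheet).
    #: "local_normal": surface normals built from the lattice's own bonds
    #: (fully internal; exact force/torque balance, but an open sheet can
    #: unroll freely).
    dihedral_reference: str = "tube_axis"

    # -- integrator / thermostat ------------------------------------------
    dt: float = 0.1
    convergence_tol: float = 1e-4   # internal energy units
    #: average kinetic energy per monomer maintained by velocity rescaling,
    #: internal energy units (default 0.5 k_BT per monomer: a gentle quench;
    #: equilibrium energies are insensitive to it, see docs/methods.md).
    kinetic_energy_target: float = 0.5 * KBT_300K
    #: zero the velocities whenever they point uphill (total power F.v < 0).
    #: Plain constant-kinetic-energy dynamics is marginally damped and can
    #: orbit a minimum indefinitely; the uphill reset turns the integrator
    #: into a robust quench while leaving the minima themselves untouched.
    uphill_reset: bool = True
    kBT_internal: float = KBT_300K
    max_steps: int = 200_000
    divergence_factor: float = 1e3

    rng_seed: int = 0

    # -- derived geometry (filled by derive_geometry) ----------------------
    cylinder_radius: float | None = None   # nm
    helical_rise: float | None = None      # nm per lateral step
    lateral_chord: float | None = None     # nm
    r0_diag_short: float | None = None     # nm
    r0_diag_long: float | None = None      # nm

    def __post_init__(self) -> None:
        self.validate()
        if self.r0_diag_short is None:
            derive_geometry(self, inplace=True)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        positive = [
            "k_long_stretch", "k_lat_stretch", "k_diag_stretch",
            "k_long_bend", "k_lat_bend", "k_long_dihedral", "k_lat_dihedral",
            "r0_long", "r0_lat", "monomer_mass", "dt", "convergence_tol",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_protofilaments <= 2:
            raise ValueError("n_protofilaments must be > 2")
        if self.pitch_monomers < 0:
            raise ValueError("pitch_monomers must be >= 0")
        if self.theta0_long_GDP <= self.theta0_long_GTP:
            raise ValueError(
                "theta0_long_GDP must exceed theta0_long_GTP: "
                "hydrolysis increases the intrinsic curvature"
            )
        if self.lateral_rest_convention not in ("nominal", "chord"):
            raise ValueError("lateral_rest_convention must be 'nominal' or 'chord'")
        if self.dihedral_reference not in ("tube_axis", "local_normal"):
            raise ValueError(
                "dihedral_reference must be 'tube_axis' or 'local_normal'")
        if self.kinetic_energy_target < 0:
            raise ValueError("kinetic_energy_target must be >= 0")

    # -- convenience -------------------------------------------------------
    @property
    def lateral_rest_length(self) -> float:
        """Rest length used by the lateral stretch terms, nm."""
        if self.lateral_rest_convention == "chord":
            if self.lateral_chord is None:
                derive_geometry(self, inplace=True)
            return float(self.lateral_chord)
        return self.r0_lat

    def theta0_long(self, hydrolyzed: bool) -> float:
        """Equilibrium longitudinal bend angle in radians for one state."""
        deg = self.theta0_long_GDP if hydrolyzed else self.theta0_long_GTP
        return math.radians(deg)

    def copy(self, **changes: Any) -> "ModelParams":
        new = dataclasses.replace(self, **changes)
        # re-derive geometry if a geometric input changed
        geometric = {"n_protofilaments", "pitch_monomers", "r0_long", "r0_lat"}
        if geometric & set(changes):
            derive_geometry(new, inplace=True)
        return new

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def derive_geometry(params: ModelParams, inplace: bool = False) -> ModelParams:
    """Fill in the diagonal rest lengths, cylinder radius and helical rise.

    The tube is a cylinder of circumference ``n * r0_lat`` (the lateral
    interval read as an arc length); lateral neighbours are separated by the
    chord ``c = 2 R sin(pi/n)`` and rise by ``h = pitch * r0_long / n`` per
    step.  A diagonal neighbour combines one lateral chord with a
    longitudinal offset of ``r0_long -/+ h``::

        r0_diag_short = sqrt(c^2 + (r0_long - h)^2)
        r0_diag_long  = sqrt(c^2 + (r0_long + h)^2)

    For the default lattice this yields 5.9988 nm and 7.1242 nm.
    """
    n = params.n_protofilaments
    if n <= 2:
        raise ValueError("geometry requires more than 2 protofilaments")
    if params.r0_long <= 0 or params.r0_lat <= 0:
        raise ValueError("rest lengths must be strictly positive")
    target = params if inplace else dataclasses.replace(params)
    radius = n * params.r0_lat / (2.0 * math.pi)
    rise = params.pitch_monomers * params.r0_long / n
    chord = 2.0 * radius * math.sin(math.pi / n)
    target.cylinder_radius = radius
    target.helical_rise = rise
    target.lateral_chord = chord
    target.r0_diag_short = math.hypot(chord, params.r0_long - rise)
    target.r0_diag_long = math.hypot(chord, params.r0_long + rise)
    return target


# ---------------------------------------------------------------------------
# configuration file round trip
# ---------------------------------------------------------------------------

_DERIVED_FIELDS = (
    "cylinder_radius", "helical_rise", "lateral_chord",
    "r0_diag_short", "r0_diag_long",
)

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def params_from_dict(data: dict[str, Any]) -> ModelParams:
    """Build validated parameters from a plain mapping.

    Unknown keys are rejected so that typos in configuration files fail
    loudly rather than silently falling back to defaults.
    """
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**data)


def load_params(path: str) -> ModelParams:
    """Load parameters from a YAML file; unset fields take the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return params_from_dict(data)


def save_params(params: ModelParams, path: str) -> None:
    data = {
        k: v for k, v in params.to_dict().items() if k not in _DERIVED_FIELDS
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
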