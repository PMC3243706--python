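import math

import numpy as np
import pytest

from mtsheet import ModelParams
from mtsheet.energetics import (EnergyBreakdown, EnergyModel, bend_angle,
                                harmonic_energy,
                                lateral_dihedral_angle_axis,
                                longitudinal_dihedral_angle_axis)
from mtsheet.io import make_fixture
from mtsheet.lattice import GDP, Lattice, Conformation, build_topology

from oracle import total_energy_oracle


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,dev,expected", [
    (3.0, 0.0, 0.0),
    (3.0, 0.1, 0.015),
    (2.0, math.radians(13.0), 0.5 * 2.0 * math.radians(13.0) ** 2),
])
def test_harmonic_energy(k, dev, expected):
    assert harmonic_energy(k, dev) == pytest.approx(expected, rel=1e-12)


def test_harmonic_energy_rejects_negative_stiffness():
    with pytest.raises(ValueError):
        harmonic_energy(-1.0, 0.1)


def test_bend_angle_straight_chain():
    assert bend_angle([0, 0, 0], [0, 0, 4], [0, 0, 8]) == pytest.approx(
        0.0, abs=1e-5)


def test_bend_angle_right_angle():
    assert bend_angle([4, 0, 0], [0, 0, 0], [0, 4, 0]) == pytest.approx(
        math.pi / 2, rel=1e-9)


def test_bend_angle_degenerate_raises():
    with pytest.raises(ValueError):
        bend_angle([1, 1, 1], [1, 1, 1], [0, 0, 1])


def test_equilibrium_gdp_kink_has_zero_energy(params):
    """Three monomers at consecutive 18-degree kinks sit at the GDP rest
    angle, so the bend deviation and energy vanish."""
    t0 = math.radians(18.0)
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([0.0, 0.0, 4.0])
    step = 4.0 * np.array([math.sin(t0), 0.0, math.cos(t0)])
    c = b + step
    theta = bend_angle(a, b, c)
    assert theta == pytest.approx(t0, rel=1e-9)
    assert harmonic_energy(params.k_long_bend,
                           theta - t0) == pytest.approx(0.0, abs=1e-15)


def test_longitudinal_dihedral_zero_for_radial_bend():
    """A chain bending inside its radial plane carries no twist."""
    # protofilament along z at x = 10, bending outward (+x)
    a = np.array([10.0, 0.0, 0.0])
    b = np.array([10.0, 0.0, 4.0])
    c = b + 4.0 * np.array([math.sin(0.3), 0.0, math.cos(0.3)])
    theta = longitudinal_dihedral_angle_axis(a, b, c)
    assert theta == pytest.approx(0.0, abs=1e-9)


def test_longitudinal_dihedral_tracks_twist():
    """Rigidly twisting the protofilament about the tube axis rotates its
    bending plane out of the radial plane by about the twist per step."""
    r = 10.0
    kink = 0.3

    def chain(phi):
        pts = []
        for k in range(3):
            ang = k * phi
            x = np.array([r * math.cos(ang), r * math.sin(ang), 4.0 * k])
            pts.append(x)
        # add outward kink to the last monomer so the bend plane exists
        pts[2] = pts[1] + (pts[2] - pts[1]) + 4.0 * math.sin(kink) * np.array(
            [math.cos(2 * phi), math.sin(2 * phi), 0.0])
        return pts

    small = longitudinal_dihedral_angle_axis(*chain(0.02))
    large = longitudinal_dihedral_angle_axis(*chain(0.04))
    assert small != 0.0
    assert large == pytest.approx(2.0 * small, rel=0.1)


def test_dihedral_mirror_antisymmetry():
    """Reflection flips the sign of the twist but not its magnitude."""
    rng = np.random.default_rng(3)
    pts = [np.array([10, 0, 0]) + rng.normal(0, 1.5, 3) for _ in range(3)]
    mirror = [p * np.array([1.0, -1.0, 1.0]) for p in pts]
    t1 = lateral_dihedral_angle_axis(*pts)
    t2 = lateral_dihedral_angle_axis(*mirror)
    assert t2 == pytest.approx(-t1, rel=1e-9)


# ---------------------------------------------------------------------------
# whole-model checks
# ---------------------------------------------------------------------------

def test_single_dimer_at_rest_has_zero_energy(params):
    lat = Lattice(1, params.pitch_monomers, wrap_seam=False)
    lat.add_monomer(0, 0)
    lat.add_monomer(0, 1)
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, params.r0_long]])
    conf = Conformation(pos, np.zeros_like(pos), np.full(2, 55.0))
    breakdown = EnergyModel(lat, params).compute(conf, with_forces=False)[0]
    assert breakdown.e_total == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("reference", ["tube_axis", "local_normal"])
def test_energy_matches_bruteforce_oracle(reference, planar):
    """Model energies equal the independent per-term numpy summation."""
    base = ModelParams(dihedral_reference=reference)
    lat, conf = planar
    rng = np.random.default_rng(11)
    conf.positions = conf.positions + rng.normal(0, 0.08,
                                                 conf.positions.shape)
    model = EnergyModel(lat, base)
    breakdown = model.compute(conf, with_forces=False)[0]
    expected = total_energy_oracle(lat, conf, base, model.topology)
    for name, value in expected.items():
        assert getattr(breakdown, name) == pytest.approx(
            value, rel=1e-9, abs=1e-12), name


def test_energy_matches_oracle_on_tube(params):
    lat, conf = make_fixture("tube_13xN", params, n_turns=4)
    rng = np.random.default_rng(5)
    conf.positions = conf.positions + rng.normal(0, 0.05,
                                                 conf.positions.shape)
    model = EnergyModel(lat, params)
    breakdown = model.compute(conf, with_forces=False)[0]
    expected = total_energy_oracle(lat, conf, params, model.topology)
    assert breakdown.e_total == pytest.approx(expected["e_total"], rel=1e-9)


def test_breakdown_sums_and_nonnegative(params, perturbed_planar):
    lat, conf = perturbed_planar
    breakdown = EnergyModel(lat, params).compute(conf, with_forces=False)[0]
    total = sum(getattr(breakdown, c) for c in EnergyBreakdown.COMPONENTS)
    assert breakdown.e_total == pytest.approx(total, rel=1e-10)
    for c in EnergyBreakdown.COMPONENTS:
        assert getattr(breakdown, c) >= 0.0


@pytest.mark.parametrize("reference", ["tube_axis", "local_normal"])
def test_forces_are_energy_gradient(reference, planar):
    """Analytic forces match central finite differences to 1e-6 relative."""
    base = ModelParams(dihedral_reference=reference)
    lat, conf = planar
    rng = np.random.default_rng(13)
    pos = conf.positions + rng.normal(0, 0.06, conf.positions.shape)
    model = EnergyModel(lat, base)
    forces = model.compute(pos)[1]
    h = 1e-5
    for _ in range(25):
        i = int(rng.integers(pos.shape[0]))
        d = int(rng.integers(3))
        pp = pos.copy()
        pp[i, d] += h
        pm = pos.copy()
        pm[i, d] -= h
        fd = -(model.energy(pp) - model.energy(pm)) / (2 * h)
        assert forces[i, d] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_net_force_and_torque_internal_convention(perturbed_planar):
    """With the fully internal dihedral convention every term obeys
    Newton's third law: net force and torque vanish to machine precision."""
    p = ModelParams(dihedral_reference="local_normal")
    lat, conf = perturbed_planar
    forces = EnergyModel(lat, p).compute(conf)[1]
    assert np.abs(forces.sum(axis=0)).max() < 1e-10
    tau = np.cross(conf.positions, forces).sum(axis=0)
    assert np.abs(tau).max() < 1e-9


def test_net_force_and_torque_axis_convention(params):
    """Axis-referenced dihedrals preserve the axial symmetries exactly;
    the transverse residual is bounded by the (small) dihedral terms."""
    lat, conf = make_fixture("tube_13xN", params, n_turns=4)
    rng = np.random.default_rng(2)
    conf.positions = conf.positions + rng.normal(0, 0.03,
                                                 conf.positions.shape)
    forces = EnergyModel(lat, params).compute(conf)[1]
    netf = forces.sum(axis=0)
    tau = np.cross(conf.positions - conf.axis_origin, forces).sum(axis=0)
    # exact along the axis (translation/rotation symmetry survives)
    assert abs(netf[2]) < 1e-10
    assert abs(tau[2]) < 1e-9
    # transverse residual only from the weak dihedral couplings
    assert np.abs(netf[:2]).max() < 0.5
    # with dihedral constants zero, everything is internal again
    p0 = params.copy(k_long_dihedral=1e-12, k_lat_dihedral=1e-12)
    forces0 = EnergyModel(lat, p0).compute(conf)[1]
    assert np.abs(forces0.sum(axis=0)).max() < 1e-9
    tau0 = np.cross(conf.positions, forces0).sum(axis=0)
    assert np.abs(tau0).max() < 1e-8


def test_frame_invariance(params):
    """Rigid rotation+translation (axis transformed with the frame) leaves
    every energy component unchanged to 1e-9 relative."""
    lat, conf = make_fixture("tube_13xN", params, n_turns=4)
    rng = np.random.default_rng(4)
    conf.positions = conf.positions + rng.normal(0, 0.05,
                                                 conf.positions.shape)
    model = EnergyModel(lat, params)
    ref = model.compute(conf, with_forces=False)[0]
    angle = 0.7
    axis = np.array([1.0, 2.0, 0.5])
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K
    moved = conf.transform(rotation=rot, translation=np.array([5., -3., 11.]))
    out = model.compute(moved, with_forces=False)[0]
    for c in EnergyBreakdown.COMPONENTS + ("e_total",):
        assert getattr(out, c) == pytest.approx(
            getattr(ref, c), rel=1e-9, abs=1e-12), c


def test_energy_additivity_of_terms(params, perturbed_planar):
    """Deleting one topology term lowers the total by that term's energy."""
    lat, conf = perturbed_planar
    model = EnergyModel(lat, params)
    full = model.energy(conf)
    t = model.topology
    # remove the first lateral stretch pair
    i, j = t.stretch_lat[0]
    d = np.linalg.norm(conf.positions[i] - conf.positions[j])
    term = harmonic_energy(params.k_lat_stretch, d - params.lateral_rest_length)
    import dataclasses
    reduced = dataclasses.replace(t, stretch_lat=t.stretch_lat[1:])
    partial = EnergyModel(lat, params, topology=reduced).energy(conf)
    assert full - partial == pytest.approx(term, rel=1e-9)


def test_nucleotide_switch_touches_only_longitudinal_bend(params):
    """Hydrolyzing one tubulin changes e_long_bend only, through the bend
    terms centred on that monomer."""
    lat, conf = make_fixture("tube_13xN", params.copy(), n_turns=4)
    rng = np.random.default_rng(6)
    conf.positions = conf.positions + rng.normal(0, 0.02,
                                                 conf.positions.shape)
    lat.nucleotide[:] = 0   # all GTP
    before = EnergyModel(lat, params).compute(conf, with_forces=False)[0]
    g = lat.gid(4, 6)
    lat.hydrolyze(g)
    after = EnergyModel(lat, params).compute(conf, with_forces=False)[0]
    for c in EnergyBreakdown.COMPONENTS:
        if c == "e_long_bend":
            assert getattr(after, c) != pytest.approx(getattr(before, c))
        else:
            assert getattr(after, c) == pytest.approx(
                getattr(before, c), rel=1e-12), c
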