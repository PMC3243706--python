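import math

import numpy as np
import pytest

from mtsheet import ModelParams
from mtsheet.energetics import EnergyModel
from mtsheet.lattice import Conformation, Lattice
from mtsheet.relaxation import (DivergenceError, RelaxationTrace,
                                rms_converged, relax, verlet_step)


def two_particle_system(params, sep):
    """One longitudinal spring between two monomers."""
    lat = Lattice(1, params.pitch_monomers, wrap_seam=False)
    lat.add_monomer(0, 0)
    lat.add_monomer(0, 1)
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, sep]])
    conf = Conformation(pos, np.zeros_like(pos),
                        np.full(2, params.monomer_mass))
    return lat, conf


def test_zero_force_zero_velocity_is_fixed_point(params):
    lat, conf = two_particle_system(params, params.r0_long)
    model = EnergyModel(lat, params)
    before = conf.positions.copy()
    verlet_step(model, conf, params)
    assert np.array_equal(conf.positions, before)
    assert np.all(conf.velocities == 0.0)


def test_verlet_matches_harmonic_oscillator(params):
    """With the thermostat off, the stretched pair oscillates at the
    analytic frequency omega = sqrt(k / mu), mu the reduced mass."""
    p = params.copy(uphill_reset=False)
    amp = 0.1
    lat, conf = two_particle_system(p, p.r0_long + amp)
    model = EnergyModel(lat, p)
    mu = p.monomer_mass / 2.0
    omega = math.sqrt(p.k_long_stretch / mu)
    forces = None
    n_steps = 300
    for _ in range(n_steps):
        forces, _ = verlet_step(model, conf, p, forces=forces,
                                rescale=False)
    t = n_steps * p.dt
    expected = p.r0_long + amp * math.cos(omega * t)
    actual = conf.positions[1, 2] - conf.positions[0, 2]
    # Verlet phase error is O(dt^2) per period
    assert actual == pytest.approx(expected, abs=5e-3)


def test_rescaling_sets_exact_kinetic_energy(params):
    lat, conf = two_particle_system(params, params.r0_long + 0.2)
    model = EnergyModel(lat, params)
    p = params.copy(uphill_reset=False)
    verlet_step(model, conf, p)
    ke = 0.5 * float(np.sum(conf.masses
                            * np.sum(conf.velocities ** 2, axis=1)))
    target = p.kinetic_energy_target * conf.n_monomers
    assert ke == pytest.approx(target, rel=1e-12)


def test_convergence_criterion_identity_case():
    """A constant energy series trivially satisfies the RMS rule."""
    assert rms_converged([5.0] * 20, tol=1e-4)
    assert not rms_converged(list(np.linspace(10, 5, 20)), tol=1e-4)
    assert not rms_converged([5.0] * 10, tol=1e-4)   # window too short


def test_relax_from_equilibrium_is_quick_and_flat(params):
    lat, conf = two_particle_system(params, params.r0_long)
    relaxed, trace = relax(lat, conf, params, max_steps=1000)
    assert trace.converged
    assert trace.steps_taken <= 25
    assert trace.final_energy == pytest.approx(trace.initial_energy,
                                               abs=1e-12)
    assert trace.peak_energy == pytest.approx(trace.initial_energy,
                                              abs=1e-12)


def test_relax_restores_displaced_monomer(params, planar):
    """A displaced monomer returns to (near) its relaxed site."""
    lat, conf = planar
    # first find the fixture's own equilibrium
    ref, trace0 = relax(lat, conf, params, max_steps=50_000)
    assert trace0.converged
    g = 5   # middle monomer
    kicked = ref.copy()
    kicked.positions[g] += np.array([0.0, 0.0, 0.1])
    relaxed, trace = relax(lat, kicked, params, max_steps=50_000)
    assert trace.converged
    assert trace.final_energy <= trace.initial_energy + 1e-9
    assert np.linalg.norm(relaxed.positions[g] - ref.positions[g]) < 1e-2


def test_relax_is_idempotent(params, planar):
    lat, conf = planar
    first, trace1 = relax(lat, conf, params, max_steps=50_000)
    second, trace2 = relax(lat, first, params, max_steps=50_000)
    assert abs(trace2.final_energy - trace1.final_energy) \
        < 10 * params.convergence_tol


def test_symplectic_energy_conservation(params):
    """Thermostat off: total (potential + kinetic) energy errors stay
    bounded over a thousand steps and shrink as O(dt^2)."""

    def max_drift(dt):
        p = params.copy(uphill_reset=False, dt=dt)
        lat, conf = two_particle_system(p, p.r0_long + 0.15)
        model = EnergyModel(lat, p)

        def total(conf, e_pot):
            ke = 0.5 * float(np.sum(conf.masses
                                    * np.sum(conf.velocities ** 2, axis=1)))
            return e_pot + ke

        forces = None
        e0 = total(conf, model.energy(conf))
        drift = 0.0
        for _ in range(1000):
            forces, breakdown = verlet_step(model, conf, p, forces=forces,
                                            rescale=False)
            drift = max(drift, abs(total(conf, breakdown.e_total) - e0))
        return drift, e0

    coarse, e0 = max_drift(0.1)
    fine, _ = max_drift(0.05)
    assert coarse < 1e-3 * e0          # bounded, no secular drift
    assert fine < 0.35 * coarse        # halving dt quarters the error


def test_divergence_aborts(params):
    p = params.copy(dt=20.0, divergence_factor=10.0)   # wildly unstable
    lat, conf = two_particle_system(p, p.r0_long + 1.0)
    with pytest.raises(DivergenceError):
        relax(lat, conf, p, max_steps=500)


def test_trace_invariants(params, planar):
    lat, conf = planar
    _, trace = relax(lat, conf, params, max_steps=50_000)
    assert trace.peak_energy >= trace.final_energy
    assert len(trace.energies) >= 2
    assert trace.record_steps is not None
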