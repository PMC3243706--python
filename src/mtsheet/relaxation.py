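"""Energy minimisation by velocity-Verlet integration with velocity rescaling.

After every discrete event (assembly, closure, hydrolysis) the perturbed
conformation is driven to its new equilibrium: positions advance by
velocity-Verlet steps of size ``dt`` and the velocities are rescaled each
step by a single scalar so the average kinetic energy per monomer stays at
``kinetic_energy_target``.  The constant small kinetic energy acts as a
gentle quench: the system flows downhill at a bounded speed, and the
potential-energy trace passes over any transient barrier on its way to the
minimum.

Convergence follows the root-mean-square rule: once the RMS of the total
potential energy over the last ten steps differs from the RMS over the
last twenty by less than ``convergence_tol``, the state is declared
equilibrated.  Velocities are zeroed on termination so that successive
relaxations are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energetics import EnergyModel
from .lattice import Lattice, Conformation
from .params import ModelParams


@dataclass
class RelaxationTrace:
    """Recorded total potential energy of one relaxation, plus outcome.

    ``peak`` is the maximum e_total over *every* step taken, even when the
    recorded series is subsampled (``record_every > 1``).
    """

    energies: np.ndarray          # recorded e_total series, nN*nm
    converged: bool
    steps_taken: int
    peak: float | None = None
    #: optional recorded seven-component series, shape (n_recorded, 7),
    #: columns ordered as EnergyBreakdown.COMPONENTS
    components: np.ndarray | None = None
    #: steps at which the recorded values were taken
    record_steps: np.ndarray | None = None

    @property
    def peak_energy(self) -> float:
        if self.peak is not None:
            return float(self.peak)
        return float(np.max(self.energies))

    @property
    def initial_energy(self) -> float:
        return float(self.energies[0])

    @property
    def final_energy(self) -> float:
        return float(self.energies[-1])


class DivergenceError(RuntimeError):
    """Relaxation energy grew beyond the configured bound."""


def rms_converged(energies, tol: float) -> bool:
    """The convergence rule on a window of at least 20 energies.

    Compares the RMS of the last ten against the RMS of the last twenty
    values of the total potential energy.
    """
    if len(energies) < 20:
        return False
    e = np.asarray(energies[-20:], dtype=float)
    rms10 = math.sqrt(float(np.mean(e[-10:] ** 2)))
    rms20 = math.sqrt(float(np.mean(e ** 2)))
    return abs(rms10 - rms20) < tol


def verlet_step(model: EnergyModel, conf: Conformation, params: ModelParams,
                forces: np.ndarray | None = None,
                rescale: bool = True):
    """Advance one velocity-Verlet step in place.

    Returns ``(new_forces, breakdown)`` with the energy breakdown at the
    new positions.

    ``forces`` are the forces at the current positions (recomputed when not
    supplied).  After the step the velocities are rescaled by one scalar so
    the mean kinetic energy per monomer equals ``kinetic_energy_target``;
    zero velocities (an exact fixed point at zero force) are left alone.
    """
    if params.dt <= 0:
        raise ValueError("dt must be positive")
    if forces is None:
        forces = model.compute(conf)[1]
    dt = params.dt
    m = conf.masses[:, None]
    v_half = conf.velocities + 0.5 * dt * forces / m
    conf.positions += dt * v_half
    if not np.all(np.isfinite(conf.positions)):
        worst = int(np.argmax(np.linalg.norm(forces, axis=1)))
        raise DivergenceError(
            f"non-finite positions; largest force on monomer {worst}")
    breakdown, new_forces, _ = model.compute(conf)
    conf.velocities = v_half + 0.5 * dt * new_forces / m
    if rescale:
        if params.uphill_reset and \
                float(np.sum(new_forces * conf.velocities)) < 0.0:
            conf.velocities[:] = 0.0
        else:
            ke = 0.5 * float(np.sum(conf.masses
                                    * np.sum(conf.velocities ** 2, axis=1)))
            target = params.kinetic_energy_target * conf.n_monomers
            if ke > 0.0 and target >= 0.0:
                conf.velocities *= math.sqrt(target / ke)
    return new_forces, breakdown


def relax(lat_or_model, conf: Conformation, params: ModelParams,
          max_steps: int | None = None,
          record_every: int = 1,
          record_components: bool = False) -> tuple[Conformation, RelaxationTrace]:
    """Drive ``conf`` to equilibrium; returns the relaxed copy and its trace.

    ``lat_or_model`` may be a :class:`Lattice` (topology built internally)
    or a prebuilt :class:`EnergyModel`.  The input conformation is not
    modified.  ``max_steps`` defaults to ``params.max_steps``; if the rule
    has not triggered by then the trace is returned with
    ``converged=False``.  Energy growth beyond
    ``divergence_factor * max(|E0|, 1)`` raises :class:`DivergenceError`.
    """
    model = lat_or_model if isinstance(lat_or_model, EnergyModel) \
        else EnergyModel(lat_or_model, params)
    if max_steps is None:
        max_steps = params.max_steps
    if max_steps < 20:
        raise ValueError("max_steps must be at least 20 (convergence window)")
    work = conf.copy()
    bd0, forces, _ = model.compute(work)
    e0 = bd0.e_total
    bound = params.divergence_factor * max(abs(e0), 1.0)
    energies = [e0]
    comp_rows = [[getattr(bd0, c) for c in bd0.COMPONENTS]]
    rec_steps = [0]
    window: list[float] = [e0]
    converged = False
    steps = 0
    peak = e0
    for step in range(1, max_steps + 1):
        forces, bd = verlet_step(model, work, params, forces=forces)
        e = bd.e_total
        steps = step
        peak = max(peak, e)
        window.append(e)
        if len(window) > 20:
            window.pop(0)
        recorded = step % record_every == 0 or step == max_steps
        if recorded:
            energies.append(e)
            rec_steps.append(step)
            if record_components:
                comp_rows.append([getattr(bd, c) for c in bd.COMPONENTS])
        if e > bound:
            raise DivergenceError(
                f"energy {e:.3g} exceeded divergence bound {bound:.3g} "
                f"at step {step}")
        if step >= 20 and rms_converged(window, params.convergence_tol):
            converged = True
            if not recorded:
                energies.append(e)
                rec_steps.append(step)
                if record_components:
                    comp_rows.append([getattr(bd, c) for c in bd.COMPONENTS])
            break
    work.velocities[:] = 0.0
    trace = RelaxationTrace(
        np.asarray(energies), converged, steps, peak=peak,
        components=np.asarray(comp_rows) if record_components else None,
        record_steps=np.asarray(rec_steps),
    )
    return work, trace
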