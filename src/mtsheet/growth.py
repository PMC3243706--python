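"""Experiment presets: closure sequences, sweeps, and Tetris-like growth.

Every preset starts from a form-found equilibrium sheet-ended microtubule
(:func:`prepare_sheet_state`), runs a sequence of discrete events with
relaxation in between, and reports activation barriers and energy
steppings per closure.  All presets are deterministic given a parameter
set and a seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import SweepResult, extract_barrier_and_stepping
from .energetics import EnergyModel
from .events import (AssemblySite, ClosureResult, EventRecord,
                     apply_hydrolysis, attempt_assembly,
                     candidate_assembly_energies, close_monomer_pair)
from .lattice import (GDP, GTP, Conformation, FullyZippedError, Lattice,
                      build_microtubule)
from .params import ModelParams
from .relaxation import RelaxationTrace, relax

#: default problem size of the standard experiment: a 10-helical-turn
#: closed body (30 monomers per protofilament) plus the ten-monomer sheet.
DEFAULT_BODY_MONOMERS = 30
DEFAULT_SHEET_MONOMERS = 10


@dataclass
class SheetState:
    """A form-found equilibrium sheet-ended microtubule."""

    lattice: Lattice
    conformation: Conformation
    e0: float                  # equilibrium energy, nN*nm
    params: ModelParams
    trace: RelaxationTrace | None = None

    def copy(self) -> "SheetState":
        return SheetState(self.lattice.copy(), self.conformation.copy(),
                          self.e0, self.params, self.trace)


def apply_sheet_pattern(lat: Lattice, pattern: str,
                        sheet_monomers: int) -> None:
    """Assign the nucleotide pattern of the sheet region in place.

    ``gtp``
        all sheet tubulins GTP (the standard scenario).
    ``half_gdp``
        the lower half of the sheet is hydrolyzed, the upper half GTP
        (an ordered GTP cap of half the sheet length).
    ``interlaced``
        a GDP spiral through an otherwise GTP sheet: the n-th tubulin
        (from the sheet bottom) of the n-th protofilament is GDP, the
        count wrapping and doubling beyond the 10th protofilament.
    """
    n = lat.n_pf
    top = {p: lat.pf_len(p) for p in range(n)}
    if pattern == "gtp":
        return
    if pattern == "half_gdp":
        half = sheet_monomers // 2
        for p in range(n):
            for k in range(sheet_monomers):
                if k < half:
                    g = lat.gid(p, top[p] - sheet_monomers + k)
                    if g is not None:
                        lat.hydrolyze(g)
        return
    if pattern == "interlaced":
        for idx in range(1, n + 1):          # 1-based protofilament count
            p = idx - 1
            marks = [(idx - 1) % sheet_monomers]
            if idx > 10:
                marks.append(idx % sheet_monomers)
            for k in marks:
                g = lat.gid(p, top[p] - sheet_monomers + k)
                if g is not None:
                    lat.hydrolyze(g)
        return
    raise ValueError(f"unknown sheet pattern {pattern!r}")


def prepare_sheet_state(params: ModelParams,
                        body_monomers: int = DEFAULT_BODY_MONOMERS,
                        sheet_monomers: int = DEFAULT_SHEET_MONOMERS,
                        sheet_pattern: str = "gtp",
                        max_steps: int | None = None) -> SheetState:
    """Build and form-find the equilibrium starting state of an experiment.

    The relaxed state (not the construction guess) defines the reference
    equilibrium energy E0.
    """
    lat, conf = build_microtubule(params, body_monomers, sheet_monomers)
    apply_sheet_pattern(lat, sheet_pattern, sheet_monomers)
    model = EnergyModel(lat, params)
    relaxed, trace = relax(model, conf, params, max_steps=max_steps)
    if not trace.converged:
        raise RuntimeError("form-finding did not converge; raise max_steps")
    return SheetState(lat, relaxed, trace.final_energy, params, trace)


# ---------------------------------------------------------------------------
# closure sequence
# ---------------------------------------------------------------------------

def run_closure_sequence(params: ModelParams,
                         n_closures: int,
                         state: SheetState | None = None,
                         hydrolysis_rule: str = "synchronous_turn",
                         rng: np.random.Generator | None = None,
                         threshold: float = 0.5,
                         body_monomers: int = DEFAULT_BODY_MONOMERS,
                         sheet_monomers: int = DEFAULT_SHEET_MONOMERS,
                         sheet_pattern: str = "gtp",
                         max_steps: int | None = None,
                         record_every: int = 20,
                         record_components: bool = True,
                         ) -> tuple[SweepResult, SheetState]:
    """Zip ``n_closures`` successive seam monomer pairs.

    Each closure starts from the previous equilibrium; barriers and
    steppings are recorded per closure together with the seven-component
    energy series.  With ``n_closures=0`` the state is returned unchanged
    and the result is empty.
    """
    if state is None:
        state = prepare_sheet_state(params, body_monomers, sheet_monomers,
                                    sheet_pattern, max_steps=max_steps)
    state = state.copy()
    labels, barriers, steppings, traces = [], [], [], []
    for i in range(n_closures):
        conf, res = close_monomer_pair(
            state.lattice, state.conformation, params,
            hydrolysis_rule=hydrolysis_rule, rng=rng, threshold=threshold,
            e_before=state.e0, max_steps=max_steps,
            record_every=record_every, record_components=record_components)
        state.conformation = conf
        state.e0 = res.e_after
        labels.append(i)
        barriers.append(res.barrier_kbt)
        steppings.append(res.stepping_kbt)
        traces.append(res.trace)
    result = SweepResult(labels, barriers, steppings, traces,
                         meta={"hydrolysis_rule": hydrolysis_rule,
                               "sheet_pattern": sheet_pattern})
    return result, state


# ---------------------------------------------------------------------------
# sheet-length sweep (conformational cap length)
# ---------------------------------------------------------------------------

def run_sheet_length_sweep(params: ModelParams,
                           lengths=range(1, 11),
                           total_monomers: int | None = None,
                           max_steps: int | None = None,
                           record_every: int = 20,
                           ) -> SweepResult:
    """One closure per sheet length, at equal total protofilament length.

    Returns barrier and stepping versus sheet length (monomers).  The
    plateau across long sheets and the drop below it locate the minimum
    conformational cap length (see
    :func:`mtsheet.analysis.minimum_stable_cap`).
    """
    lengths = list(lengths)
    if total_monomers is None:
        total_monomers = DEFAULT_BODY_MONOMERS + DEFAULT_SHEET_MONOMERS
    labels, barriers, steppings, traces = [], [], [], []
    for sheet_len in lengths:
        state = prepare_sheet_state(params, total_monomers - sheet_len,
                                    sheet_len, max_steps=max_steps)
        conf, res = close_monomer_pair(
            state.lattice, state.conformation, params, e_before=state.e0,
            max_steps=max_steps, record_every=record_every)
        labels.append(sheet_len)
        barriers.append(res.barrier_kbt)
        steppings.append(res.stepping_kbt)
        traces.append(res.trace)
    return SweepResult(labels, barriers, steppings, traces,
                       meta={"total_monomers": total_monomers})


# ---------------------------------------------------------------------------
# parameter sensitivity
# ---------------------------------------------------------------------------

SENSITIVITY_CONSTANTS = ("k_diag_stretch", "k_long_dihedral",
                         "k_lat_dihedral")


def run_sensitivity_sweep(params: ModelParams, constant: str,
                          factors=(0.1, 1.0, 10.0),
                          body_monomers: int = DEFAULT_BODY_MONOMERS,
                          sheet_monomers: int = DEFAULT_SHEET_MONOMERS,
                          max_steps: int | None = None,
                          record_every: int = 20) -> SweepResult:
    """One closure per scaling factor of one empirically assumed constant.

    The three constants without direct experimental backing (diagonal
    stretch and the two dihedral stiffnesses) are scaled one at a time,
    the others staying at their defaults.
    """
    if constant not in SENSITIVITY_CONSTANTS:
        raise ValueError(f"constant must be one of {SENSITIVITY_CONSTANTS}")
    labels, barriers, steppings, traces = [], [], [], []
    for f in factors:
        varied = params.copy(**{constant: getattr(params, constant) * f})
        state = prepare_sheet_state(varied, body_monomers, sheet_monomers,
                                    max_steps=max_steps)
        conf, res = close_monomer_pair(
            state.lattice, state.conformation, varied, e_before=state.e0,
            max_steps=max_steps, record_every=record_every)
        labels.append(f)
        barriers.append(res.barrier_kbt)
        steppings.append(res.stepping_kbt)
        traces.append(res.trace)
    return SweepResult(labels, barriers, steppings, traces,
                       meta={"constant": constant})


# ---------------------------------------------------------------------------
# Tetris growth
# ---------------------------------------------------------------------------

@dataclass
class TetrisResult:
    """Event log and sheet-length series of a Tetris growth run."""

    events: list[EventRecord]
    sheet_lengths: list[float]      # mean sheet length after every event
    layers_completed: int
    stalled: bool
    monomer_counts: list[int]

    def log_lines(self) -> list[str]:
        return [ev.to_json() for ev in self.events]


def mean_sheet_length(lat: Lattice) -> float:
    """Mean number of open-sheet monomers per protofilament."""
    base = lat.sheet_base_axial
    return float(np.mean([max(lat.pf_len(p) - base, 0)
                          for p in range(lat.n_pf)]))


def run_tetris(params: ModelParams, n_layers: int,
               rng: np.random.Generator,
               state: SheetState | None = None,
               body_monomers: int = DEFAULT_BODY_MONOMERS,
               sheet_monomers: int = DEFAULT_SHEET_MONOMERS,
               policy: str = "boltzmann",
               closures_per_layer: int = 2,
               stall_limit: int = 3,
               max_steps: int | None = None,
               candidate_max_steps: int | None = None,
               ) -> tuple[TetrisResult, SheetState]:
    """Layer-by-layer growth: fill a dimer layer, then zip the seam.

    Each cycle assembles GTP dimers (energy-regulated, stochastic) onto
    the protofilaments that have not yet reached the current target level;
    once the layer is complete across all protofilaments the seam advances
    one dimer length (``closures_per_layer`` monomer-pair closures with
    synchronous hydrolysis).  If no assembly site is acceptable for
    ``stall_limit`` consecutive attempts the run terminates with
    ``stalled=True``.
    """
    if state is None:
        state = prepare_sheet_state(params, body_monomers, sheet_monomers,
                                    max_steps=max_steps)
    state = state.copy()
    lat = state.lattice
    events: list[EventRecord] = []
    sheet_series = [mean_sheet_length(lat)]
    monomer_counts = [lat.n_monomers]
    kbt = params.kBT_internal
    step = 0
    stalled = False
    layers_done = 0
    base_len = max(lat.pf_len(p) for p in range(lat.n_pf))

    def record(event: str, detail: dict, **kw) -> None:
        events.append(EventRecord(event, step, detail, **kw))
        sheet_series.append(mean_sheet_length(lat))
        monomer_counts.append(lat.n_monomers)

    from .events import add_dimer

    for layer in range(1, n_layers + 1):
        target = base_len + 2 * layer
        stall = 0
        # fill phase: only protofilaments below the current layer level
        # are candidate sites, so a completed layer is exactly 13 dimers
        while True:
            pending = [p for p in range(lat.n_pf) if lat.pf_len(p) < target]
            if not pending:
                break
            sites = candidate_assembly_energies(
                lat, state.conformation, params, e0=state.e0,
                protofilaments=pending, max_steps=candidate_max_steps)
            site, prob, draws = attempt_assembly(sites, rng, params,
                                                 policy=policy)
            step += 1
            if site is None:
                stall += 1
                record("assembly", {"accepted": False},
                       e_before=state.e0 / kbt, probability=0.0,
                       rng_draws=draws)
                if stall >= stall_limit:
                    stalled = True
                    break
                continue
            stall = 0
            add_dimer(lat, state.conformation, params,
                      site.protofilament_index)
            relaxed, tr = relax(EnergyModel(lat, params), state.conformation,
                                params, max_steps=max_steps)
            state.conformation = relaxed
            record("assembly",
                   {"accepted": True,
                    "protofilament": site.protofilament_index,
                    "site_class": site.site_class,
                    "dE_total_kbt": site.dE_total},
                   e_before=state.e0 / kbt, e_after=tr.final_energy / kbt,
                   probability=prob, rng_draws=draws)
            state.e0 = tr.final_energy
        if stalled:
            break
        # zip phase: the seam advances one dimer length
        for _ in range(closures_per_layer):
            try:
                conf, res = close_monomer_pair(
                    lat, state.conformation, params, e_before=state.e0,
                    max_steps=max_steps, record_every=50)
            except FullyZippedError:
                stalled = True
                break
            state.conformation = conf
            step += 1
            record("closure", {"pair_index": res.pair_index,
                               "n_hydrolyzed": res.n_hydrolyzed},
                   e_before=res.e_before / kbt, e_after=res.e_after / kbt,
                   barrier=res.barrier_kbt)
            state.e0 = res.e_after
        if stalled:
            break
        layers_done = layer
    result = TetrisResult(events, sheet_series, layers_done, stalled,
                          monomer_counts)
    return result, state
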