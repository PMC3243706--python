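"""Discrete growth events: dimer assembly, seam closure, GTP hydrolysis.

Growth alternates between mechanical relaxation (continuous) and three
kinds of discrete events:

* **assembly** — a GTP dimer attaches to a protofilament tip.  The decision
  couples chemistry and mechanics: the association free energy of the site
  (how many lateral bonds the incomer forms) is added to the mechanical
  strain its insertion leaves in the relaxed lattice, and only sites with a
  negative total energy change can fire, with Boltzmann-weighted selection
  among them.
* **closure** — the lowest open cross-seam monomer pair acquires the
  lateral stretch, bend and dihedral interactions, converting one step of
  sheet into tube; the transient of the subsequent relaxation *is* the
  activation barrier of the sheet-to-tube transition.
* **hydrolysis** — GTP -> GDP switches the equilibrium longitudinal bend
  angle of the affected interfaces from 5 to 18 degrees.  Hydrolysis is a
  forced event (no rate model): rules couple it to closure (synchronous
  with the newly closed turn), apply it in ordered caps, or draw it
  randomly per tubulin.

Association free energies (k_BT per dimer): longitudinal bond -19, lateral
bond -4, immobilisation penalty +11, giving -16 / -12 / -8 for gap / side /
crest sites.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .energetics import EnergyModel
from .lattice import (GDP, GTP, Conformation, FullyZippedError, Lattice,
                      build_topology)
from .params import ModelParams
from .relaxation import DivergenceError, RelaxationTrace, relax

SITE_GAP = "gap"
SITE_SIDE = "side"
SITE_CREST = "crest"


@dataclass
class AssemblySite:
    """A candidate tip position for one incoming GTP dimer."""

    protofilament_index: int
    site_class: str
    dG_assoc: float          # chemical part, k_BT
    strain: float            # mechanical part (E_n - E_0)/k_BT
    dE_total: float          # strain + dG_assoc, k_BT
    valid: bool = True


@dataclass
class EventRecord:
    """One line of the append-only event log."""

    event: str               # assembly | closure | hydrolysis
    step: int
    detail: dict
    e_before: float | None = None   # k_BT
    e_after: float | None = None    # k_BT
    barrier: float | None = None    # k_BT
    probability: float | None = None
    rng_draws: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "EventRecord":
        return cls(**json.loads(line))


# ---------------------------------------------------------------------------
# association thermodynamics
# ---------------------------------------------------------------------------

def association_energy(site_class: str, params: ModelParams) -> float:
    """Free energy of association for one dimer at a site class, k_BT.

    gap: two lateral bonds + one longitudinal; side: one lateral + one
    longitudinal; crest: longitudinal only.  The immobilisation penalty
    dG_S applies once per dimer.
    """
    if site_class == SITE_GAP:
        return 2.0 * params.dG_lat + params.dG_long + params.dG_S
    if site_class == SITE_SIDE:
        return params.dG_lat + params.dG_long + params.dG_S
    if site_class == SITE_CREST:
        return params.dG_long + params.dG_S
    raise ValueError(f"unknown site class {site_class!r}")


def classify_site(lat: Lattice, p: int) -> str:
    """Class of the tip site on protofilament ``p`` for an incoming dimer.

    Determined purely by how many sides (clockwise / counterclockwise)
    offer at least one pre-assembled lateral neighbour to the incoming
    dimer's two monomers.
    """
    j0 = lat.pf_len(p)
    left = right = False
    for j in (j0, j0 + 1):
        # neighbour existence follows the bond rules (seam only if zipped)
        if p > 0:
            left = left or lat.gid(p - 1, j) is not None
        elif lat.is_zipped(j - lat.pitch):
            left = left or lat.gid(lat.n_pf - 1, j - lat.pitch) is not None
        if p < lat.n_pf - 1:
            right = right or lat.gid(p + 1, j) is not None
        elif lat.is_zipped(j):
            right = right or lat.gid(0, j + lat.pitch) is not None
    n_sides = int(left) + int(right)
    return (SITE_CREST, SITE_SIDE, SITE_GAP)[n_sides]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def add_dimer(lat: Lattice, conf: Conformation, params: ModelParams,
              p: int, nucleotide: int = GTP) -> tuple[int, int]:
    """Append one dimer (two monomers) to the tip of protofilament ``p``.

    The new monomers continue the tip's local direction at the rest
    longitudinal separation.  Mutates ``lat`` and ``conf`` in place and
    returns the two new global ids.
    """
    j0 = lat.pf_len(p)
    if j0 >= 2:
        a = conf.positions[lat.gid(p, j0 - 2)]
        b = conf.positions[lat.gid(p, j0 - 1)]
        direction = b - a
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        tip = b
    elif j0 == 1:
        tip = conf.positions[lat.gid(p, 0)]
        direction = np.array([0.0, 0.0, 1.0])
    else:
        raise ValueError("cannot assemble onto an empty protofilament")
    g1 = lat.add_monomer(p, j0, nucleotide)
    g2 = lat.add_monomer(p, j0 + 1, nucleotide)
    new_pos = np.vstack([tip + params.r0_long * direction,
                         tip + 2.0 * params.r0_long * direction])
    conf.positions = np.vstack([conf.positions, new_pos])
    conf.velocities = np.vstack([conf.velocities, np.zeros((2, 3))])
    conf.masses = np.append(conf.masses,
                            [params.monomer_mass, params.monomer_mass])
    return g1, g2


def candidate_assembly_energies(lat: Lattice, conf: Conformation,
                                params: ModelParams,
                                e0: float | None = None,
                                protofilaments: list[int] | None = None,
                                max_steps: int | None = None,
                                ) -> list[AssemblySite]:
    """Evaluate the total energy change of a trial dimer on each tip.

    For every candidate protofilament a copy of the system receives one
    GTP dimer at the tip, is relaxed, and the equilibrium energy difference
    (in k_BT) plus the chemical association energy gives ``dE_total``.  The
    caller's lattice and conformation are never modified (trial additions
    operate on copies).  A candidate whose relaxation fails is flagged
    invalid; the others are unaffected.
    """
    if e0 is None:
        e0 = EnergyModel(lat, params).energy(conf)
    if protofilaments is None:
        protofilaments = list(range(lat.n_pf))
    sites = []
    for p in protofilaments:
        site_class = classify_site(lat, p)
        dg = association_energy(site_class, params)
        trial_lat = lat.copy()
        trial_conf = conf.copy()
        add_dimer(trial_lat, trial_conf, params, p)
        try:
            relaxed, trace = relax(trial_lat, trial_conf, params,
                                   max_steps=max_steps)
            if not trace.converged:
                raise DivergenceError("candidate relaxation did not converge")
            strain = (trace.final_energy - e0) / params.kBT_internal
            sites.append(AssemblySite(p, site_class, dg, strain,
                                      strain + dg))
        except (DivergenceError, FloatingPointError):
            sites.append(AssemblySite(p, site_class, dg, math.nan,
                                      math.nan, valid=False))
    return sites


def attempt_assembly(sites: list[AssemblySite], rng: np.random.Generator,
                     params: ModelParams,
                     policy: str = "boltzmann",
                     ) -> tuple[AssemblySite | None, float, int]:
    """Select at most one assembly site; returns (site, probability, draws).

    Sites with non-negative total energy change never fire.  Under the
    default ``boltzmann`` policy one site is drawn from the remaining
    candidates with probability proportional to ``exp(-dE_total)``.  The
    ``metropolis`` policy instead visits the negative sites in a random
    order and accepts each independently with ``min(1, exp(-dE))`` (always
    1 for negative dE, retained for completeness); ``forced`` accepts a
    uniformly random valid site regardless of sign (bookkeeping tests).
    """
    valid = [s for s in sites if s.valid]
    if policy == "forced":
        if not valid:
            return None, 0.0, 0
        idx = int(rng.integers(len(valid)))
        return valid[idx], 1.0 / len(valid), 1
    negative = [s for s in valid if s.dE_total < 0]
    if not negative:
        return None, 0.0, 0
    if policy == "metropolis":
        order = rng.permutation(len(negative))
        chosen = negative[int(order[0])]
        return chosen, 1.0, 1
    if policy != "boltzmann":
        raise ValueError(f"unknown assembly policy {policy!r}")
    de = np.array([s.dE_total for s in negative])
    w = np.exp(-(de - de.min()))
    w /= w.sum()
    idx = int(rng.choice(len(negative), p=w))
    return negative[idx], float(w[idx]), 1


# ---------------------------------------------------------------------------
# hydrolysis
# ---------------------------------------------------------------------------

def sheet_monomers(lat: Lattice) -> list[int]:
    """Global ids of monomers in the open-sheet region.

    The sheet is everything at or above the axial level of the lowest
    unzipped seam monomer on protofilament 0 (``sheet_base_axial``).
    """
    base = lat.sheet_base_axial
    return [g for g in range(lat.n_monomers) if lat.loc(g)[1] >= base]


def apply_hydrolysis(lat: Lattice, rule: str,
                     rng: np.random.Generator | None = None,
                     threshold: float = 0.5,
                     cap_layers: int | None = None) -> tuple[int, int]:
    """Apply one hydrolysis rule in place; returns (n_hydrolyzed, rng_draws).

    ``synchronous_turn``
        everything below the top of the newly closed helical turn becomes
        GDP: the hydrolysis front tracks the zip front one turn behind the
        sheet.  Call immediately after a closure.
    ``ordered_cap``
        only the top ``cap_layers`` dimer layers (2*cap_layers monomers)
        of every protofilament stay GTP; everything deeper is GDP.
    ``random``
        one uniform draw per GTP tubulin in the sheet; hydrolyze iff the
        draw exceeds ``threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    n_hyd = 0
    draws = 0
    if rule == "synchronous_turn":
        front = lat.zipped_count - 1 + lat.pitch
        for g in range(lat.n_monomers):
            if lat.loc(g)[1] <= front and lat.nucleotide[g] == GTP:
                lat.hydrolyze(g)
                n_hyd += 1
    elif rule == "ordered_cap":
        if cap_layers is None or cap_layers < 0:
            raise ValueError("ordered_cap requires cap_layers >= 0")
        keep = 2 * cap_layers
        for g in range(lat.n_monomers):
            p, j = lat.loc(g)
            if j < lat.pf_len(p) - keep and lat.nucleotide[g] == GTP:
                lat.hydrolyze(g)
                n_hyd += 1
    elif rule == "random":
        if rng is None:
            raise ValueError("random hydrolysis requires an rng")
        for g in sheet_monomers(lat):
            if lat.nucleotide[g] == GTP:
                u = float(rng.random())
                draws += 1
                if u > threshold:
                    lat.hydrolyze(g)
                    n_hyd += 1
    elif rule == "none":
        pass
    else:
        raise ValueError(f"unknown hydrolysis rule {rule!r}")
    return n_hyd, draws


# ---------------------------------------------------------------------------
# closure
# ---------------------------------------------------------------------------

@dataclass
class ClosureResult:
    """Outcome of one monomer-pair closure."""

    pair_index: int
    e_before: float            # nN*nm, pre-closure equilibrium
    e_after: float             # nN*nm, post-closure equilibrium
    barrier_kbt: float         # (peak - e_before) / k_BT
    stepping_kbt: float        # (e_after - e_before) / k_BT
    n_hydrolyzed: int
    trace: RelaxationTrace
    new_terms: dict[str, int]  # topology term-count increments


def close_monomer_pair(lat: Lattice, conf: Conformation, params: ModelParams,
                       hydrolysis_rule: str = "synchronous_turn",
                       rng: np.random.Generator | None = None,
                       threshold: float = 0.5,
                       e_before: float | None = None,
                       max_steps: int | None = None,
                       record_every: int = 1,
                       record_components: bool = False,
                       ) -> tuple[Conformation, ClosureResult]:
    """Zip the lowest open seam pair and relax to the next equilibrium.

    The pair gains the lateral stretch, bend and dihedral terms (plus
    seam diagonals when enabled); the configured hydrolysis rule fires;
    the system relaxes.  The transient peak of the relaxation above the
    pre-closure equilibrium is the activation barrier, the equilibrium
    difference the energy stepping, both in k_BT.  Mutates ``lat`` in
    place; returns the relaxed conformation and the closure record.

    Raises :class:`FullyZippedError` on a blunt tube.
    """
    counts_before = build_topology(lat, params).term_counts()
    if e_before is None:
        e_before = EnergyModel(lat, params).energy(conf)
    jp, ga, gb = lat.zip_next_pair()
    n_hyd, _ = apply_hydrolysis(lat, hydrolysis_rule, rng=rng,
                                threshold=threshold)
    model = EnergyModel(lat, params)
    counts_after = model.topology.term_counts()
    relaxed, trace = relax(model, conf, params, max_steps=max_steps,
                           record_every=record_every,
                           record_components=record_components)
    kbt = params.kBT_internal
    result = ClosureResult(
        pair_index=jp,
        e_before=e_before,
        e_after=trace.final_energy,
        barrier_kbt=(trace.peak_energy - e_before) / kbt,
        stepping_kbt=(trace.final_energy - e_before) / kbt,
        n_hydrolyzed=n_hyd,
        trace=trace,
        new_terms={k: counts_after[k] - counts_before[k]
                   for k in counts_after},
    )
    return relaxed, result
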