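"""Quantitative observables: barriers, steppings, plateaus, cap length.

The closure of one seam monomer pair leaves two numbers in the energy
trace: the *activation barrier* (transient peak of the total potential
energy above the pre-closure equilibrium) and the *energy stepping*
(difference between the two successive equilibria).  Both are reported in
k_BT.  Sweeping the sheet length and locating where the barrier falls off
its long-sheet plateau yields the minimum conformational cap length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .relaxation import RelaxationTrace


@dataclass
class SweepResult:
    """Barrier and stepping per experimental condition, in k_BT."""

    labels: list
    barriers: list[float]
    steppings: list[float]
    traces: list[RelaxationTrace] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.labels,
            "barrier_kbt": self.barriers,
            "stepping_kbt": self.steppings,
        })


def extract_barrier_and_stepping(trace: RelaxationTrace, e_before: float,
                                 params: ModelParams) -> tuple[float, float]:
    """Barrier and stepping (k_BT) of one closure relaxation trace.

    ``e_before`` is the pre-closure equilibrium energy in internal units
    (nN*nm).  The barrier is clipped below at zero: a trace started at
    equilibrium has no transient peak.
    """
    if not trace.converged:
        raise ValueError("trace did not converge; barrier undefined")
    kbt = params.kBT_internal
    barrier = max(trace.peak_energy - e_before, 0.0) / kbt
    stepping = (trace.final_energy - e_before) / kbt
    return barrier, stepping


def plateau_mean(lengths, barriers, tolerance: float = 0.1) -> tuple[float, list]:
    """Mean barrier over the longest plateau suffix of a length sweep.

    The plateau is the longest suffix of conditions (ordered by length)
    whose pairwise relative spread, (max-min)/max, stays within
    ``tolerance``.  Returns ``(mean, plateau_lengths)``.
    """
    order = np.argsort(lengths)
    lens = np.asarray(lengths)[order]
    bars = np.asarray(barriers, dtype=float)[order]
    if len(bars) == 0:
        raise ValueError("empty sweep")
    best_start = len(bars) - 1
    for start in range(len(bars) - 1, -1, -1):
        chunk = bars[start:]
        top = np.max(np.abs(chunk))
        if top == 0:
            spread = 0.0
        else:
            spread = (chunk.max() - chunk.min()) / top
        if spread <= tolerance:
            best_start = start
        else:
            break
    plateau = lens[best_start:]
    return float(np.mean(bars[best_start:])), list(plateau)


def minimum_stable_cap(sweep: SweepResult, tolerance: float = 0.1) -> int:
    """Smallest sheet length that still supports the plateau barrier.

    Sweep labels must be sheet lengths in monomers.  The plateau mean is
    taken over the longest suffix within ``tolerance``; the minimum stable
    cap is the smallest length whose barrier reaches
    ``(1 - tolerance) * plateau mean``, converted to dimer layers
    (monomers / 2, rounded up).

    Raises ``ValueError`` when no plateau is detectable (fewer than two
    conditions on the plateau and a non-flat sweep).
    """
    lengths = np.asarray(sweep.labels, dtype=float)
    barriers = np.asarray(sweep.barriers, dtype=float)
    mean, plateau = plateau_mean(lengths, barriers, tolerance)
    if len(plateau) < 2 and len(lengths) > 1:
        raise ValueError("no barrier plateau detectable in sweep")
    threshold = (1.0 - tolerance) * mean
    order = np.argsort(lengths)
    for idx in order:
        if barriers[idx] >= threshold:
            return max(1, math.ceil(lengths[idx] / 2.0))
    raise ValueError("no length reaches the plateau barrier")


def plot_closure_trace(traces, params: ModelParams, path,
                       components: bool = True) -> None:
    """Plot the energy evolution of one or more closure relaxations.

    Top panel: total potential energy (k_BT) against accumulated steps,
    with the transient barrier of each closure visible.  Bottom panel
    (when component series were recorded): the seven interaction-energy
    components on a semilogarithmic axis, reflecting their different
    orders of magnitude.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(traces, RelaxationTrace):
        traces = [traces]
    kbt = params.kBT_internal
    has_comps = components and all(t.components is not None for t in traces)
    fig, axes = plt.subplots(2 if has_comps else 1, 1, figsize=(7, 7),
                             sharex=True, squeeze=False)
    offset = 0
    from .energetics import EnergyBreakdown
    for t in traces:
        steps = (t.record_steps if t.record_steps is not None
                 else np.arange(len(t.energies))) + offset
        axes[0, 0].plot(steps, np.asarray(t.energies) / kbt, color="C3")
        if has_comps:
            for i, name in enumerate(EnergyBreakdown.COMPONENTS):
                axes[1, 0].semilogy(steps, t.components[:, i] / kbt,
                                    color=f"C{i}",
                                    label=name if offset == 0 else None)
        offset = steps[-1]
    axes[0, 0].set_ylabel(r"$E_{\rm total}$ ($k_BT$)")
    if has_comps:
        axes[1, 0].set_ylabel(r"components ($k_BT$)")
        axes[1, 0].set_xlabel("relaxation step")
        axes[1, 0].legend(fontsize=7, ncol=2)
    else:
        axes[0, 0].set_xlabel("relaxation step")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(sweep: SweepResult, path, xlabel: str = "condition") -> None:
    """Barriers and steppings per condition, side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    ax1.plot(sweep.labels, sweep.barriers, "o-")
    ax1.set_xlabel(xlabel)
    ax1.set_ylabel(r"barrier ($k_BT$)")
    ax2.plot(sweep.labels, sweep.steppings, "s-", color="C3")
    ax2.set_xlabel(xlabel)
    ax2.set_ylabel(r"stepping ($k_BT$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def trace_to_frame(trace: RelaxationTrace, params: ModelParams,
                   components: bool = True) -> pd.DataFrame:
    """Energy trace as a tidy table (step, e_total and components, k_BT)."""
    kbt = params.kBT_internal
    data = {"step": trace.record_steps
            if trace.record_steps is not None
            else np.arange(len(trace.energies)),
            "e_total_kbt": np.asarray(trace.energies) / kbt}
    if components and trace.components is not None:
        from .energetics import EnergyBreakdown
        for i, name in enumerate(EnergyBreakdown.COMPONENTS):
            data[name + "_kbt"] = trace.components[:, i] / kbt
    return pd.DataFrame(data)
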