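import numpy as np
import pytest

from mtsheet import ModelParams
from mtsheet.analysis import (SweepResult, extract_barrier_and_stepping,
                              minimum_stable_cap, plateau_mean,
                              trace_to_frame)
from mtsheet.growth import (mean_sheet_length, prepare_sheet_state,
                            run_closure_sequence, run_tetris)
from mtsheet.lattice import FullyZippedError
from mtsheet.relaxation import RelaxationTrace


def make_trace(values, converged=True):
    arr = np.asarray(values, float)
    return RelaxationTrace(arr, converged, len(arr) - 1, peak=float(arr.max()))


# ---------------------------------------------------------------------------
# barrier / stepping extraction
# ---------------------------------------------------------------------------

def test_barrier_and_stepping_from_synthetic_trace(params):
    trace = make_trace([10.0, 50.0, 12.0])
    barrier, stepping = extract_barrier_and_stepping(trace, 10.0, params)
    kbt = params.kBT_internal
    assert barrier == pytest.approx(40.0 / kbt)
    assert stepping == pytest.approx(2.0 / kbt)


def test_monotone_descent_has_zero_barrier(params):
    trace = make_trace([8.0, 6.0, 5.0, 4.9])
    barrier, stepping = extract_barrier_and_stepping(trace, 8.0, params)
    assert barrier == 0.0
    assert stepping < 0.0


def test_unconverged_trace_rejected(params):
    trace = make_trace([5.0, 4.0], converged=False)
    with pytest.raises(ValueError):
        extract_barrier_and_stepping(trace, 5.0, params)


def test_extraction_invariant_to_energy_offset(params):
    t1 = make_trace([10.0, 50.0, 12.0])
    t2 = make_trace([110.0, 150.0, 112.0])
    assert extract_barrier_and_stepping(t1, 10.0, params) == \
        pytest.approx(extract_barrier_and_stepping(t2, 110.0, params))


# ---------------------------------------------------------------------------
# plateau detection / cap length
# ---------------------------------------------------------------------------

def test_minimum_stable_cap_step_function():
    sweep = SweepResult(list(range(1, 7)), [1, 1, 1, 10, 10, 10],
                        [0] * 6)
    assert minimum_stable_cap(sweep, tolerance=0.1) == 2   # 4 monomers


def test_minimum_stable_cap_flat_sweep():
    sweep = SweepResult(list(range(1, 7)), [7.0] * 6, [0] * 6)
    assert minimum_stable_cap(sweep, tolerance=0.1) == 1


def test_minimum_stable_cap_scale_invariant():
    b = [1, 1, 1, 10, 10, 10]
    s1 = SweepResult(list(range(1, 7)), b, [0] * 6)
    s2 = SweepResult(list(range(1, 7)), [v * 137.0 for v in b], [0] * 6)
    assert minimum_stable_cap(s1, 0.1) == minimum_stable_cap(s2, 0.1)


def test_plateau_mean_longest_suffix():
    mean, plateau = plateau_mean([1, 2, 3, 4, 5, 6],
                                 [1, 1, 1, 10, 10.5, 10.2], tolerance=0.1)
    assert plateau == [4, 5, 6]
    assert mean == pytest.approx((10 + 10.5 + 10.2) / 3)


def test_trace_frame_has_components(params):
    trace = RelaxationTrace(np.array([1.0, 2.0]), True, 1, peak=2.0,
                            components=np.ones((2, 7)),
                            record_steps=np.array([0, 1]))
    frame = trace_to_frame(trace, params)
    assert len(frame) == 2
    assert "e_lat_bend_kbt" in frame.columns


# ---------------------------------------------------------------------------
# closure sequence plumbing
# ---------------------------------------------------------------------------

def test_zero_closures_is_a_noop(params):
    state = prepare_sheet_state(params, body_monomers=9, sheet_monomers=4)
    sig = state.lattice.state_signature()
    result, out = run_closure_sequence(params, 0, state=state)
    assert result.barriers == [] and result.steppings == []
    assert out.lattice.state_signature() == sig
    assert out.e0 == state.e0


# ---------------------------------------------------------------------------
# Tetris growth
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tetris_forced():
    """One forced-acceptance layer on a small sheet-ended microtubule."""
    params = ModelParams()
    rng = np.random.default_rng(17)
    result, state = run_tetris(params, n_layers=1, rng=rng,
                               body_monomers=9, sheet_monomers=4,
                               policy="forced")
    return params, result, state


def test_tetris_layer_is_13_dimers_then_2_closures(tetris_forced):
    """A completed layer is exactly 13 assembly events followed by the
    seam advancing one dimer length (two monomer-pair closures)."""
    _, result, _ = tetris_forced
    kinds = [e.event for e in result.events]
    accepted = [e for e in result.events
                if e.event == "assembly" and e.detail["accepted"]]
    closures = [e for e in result.events if e.event == "closure"]
    assert len(accepted) == 13
    assert len(closures) == 2
    assert kinds[-2:] == ["closure", "closure"]
    assert result.layers_completed == 1
    assert not result.stalled


def test_tetris_monomer_conservation(tetris_forced):
    """Monomer count rises by exactly 26 per completed layer."""
    _, result, _ = tetris_forced
    assert result.monomer_counts[-1] - result.monomer_counts[0] == 26


def test_tetris_sheet_length_constant_over_cycle(tetris_forced):
    """Fill-then-zip keeps the sheet length constant across a full cycle."""
    _, result, _ = tetris_forced
    assert result.sheet_lengths[-1] == pytest.approx(
        result.sheet_lengths[0], abs=1e-9)


def test_tetris_is_seed_deterministic():
    params = ModelParams()
    logs = []
    for _ in range(2):
        rng = np.random.default_rng(21)
        result, _ = run_tetris(params, n_layers=1, rng=rng,
                               body_monomers=9, sheet_monomers=4,
                               policy="forced")
        logs.append([e.to_json() for e in result.events])
    assert logs[0] == logs[1]


def test_closure_without_assembly_exhausts_the_sheet(params):
    """Zipping faster than assembly closes the sheet into a blunt tube."""
    from mtsheet.events import close_monomer_pair
    state = prepare_sheet_state(params, body_monomers=9, sheet_monomers=2)
    lat, conf = state.lattice, state.conformation
    lengths = [mean_sheet_length(lat)]
    with pytest.raises(FullyZippedError):
        for _ in range(10):
            conf, _ = close_monomer_pair(lat, conf, params)
            lengths.append(mean_sheet_length(lat))
    assert lengths[-1] < lengths[0]
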