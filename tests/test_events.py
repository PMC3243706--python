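import math

import numpy as np
import pytest

from mtsheet import ModelParams
from mtsheet.energetics import EnergyModel
from mtsheet.events import (AssemblySite, EventRecord, add_dimer,
                            apply_hydrolysis, association_energy,
                            attempt_assembly, candidate_assembly_energies,
                            classify_site, close_monomer_pair)
from mtsheet.lattice import (GDP, GTP, FullyZippedError, Lattice,
                             build_microtubule, build_topology)
from mtsheet.relaxation import relax


# ---------------------------------------------------------------------------
# association thermodynamics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("site_class,expected", [
    ("gap", 2 * (-4.0) + (-19.0) + 11.0),      # -16
    ("side", -4.0 + (-19.0) + 11.0),           # -12
    ("crest", -19.0 + 11.0),                   # -8
])
def test_association_energy(params, site_class, expected):
    assert association_energy(site_class, params) == expected


def test_association_energy_unknown_class(params):
    with pytest.raises(ValueError):
        association_energy("ridge", params)


def test_site_classification(params):
    """Site class counts the sides offering lateral neighbours."""
    lat, conf = build_microtubule(params, 12, 4)
    # uniform tips: no neighbour reaches above any tip -> crest everywhere
    assert classify_site(lat, 6) == "crest"
    # raise both neighbours of protofilament 6 -> gap
    add_dimer(lat, conf, params, 5)
    add_dimer(lat, conf, params, 7)
    assert classify_site(lat, 6) == "gap"
    # single-sided neighbour -> side
    assert classify_site(lat, 4) == "side"
    assert classify_site(lat, 8) == "side"
    # far away still crest
    assert classify_site(lat, 0) == "crest"


# ---------------------------------------------------------------------------
# candidate evaluation and selection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_state():
    params = ModelParams()
    lat, conf = build_microtubule(params, 9, 4)
    model = EnergyModel(lat, params)
    relaxed, trace = relax(model, conf, params)
    assert trace.converged
    return params, lat, relaxed, trace.final_energy


def test_candidates_roll_back_cleanly(small_state):
    params, lat, conf, e0 = small_state
    sig = lat.state_signature()
    pos = conf.positions.copy()
    sites = candidate_assembly_energies(lat, conf, params, e0=e0,
                                        protofilaments=[0, 5, 12])
    assert lat.state_signature() == sig
    assert np.array_equal(conf.positions, pos)
    assert len(sites) == 3
    for s in sites:
        assert s.valid
        assert s.dE_total == pytest.approx(s.strain + s.dG_assoc)


def test_crest_addition_strain_is_small(small_state):
    """An unconstrained tip extension at rest geometry is nearly
    strain-free, so dE approaches the bare crest association energy."""
    params, lat, conf, e0 = small_state
    sites = candidate_assembly_energies(lat, conf, params, e0=e0,
                                        protofilaments=[6])
    s = sites[0]
    assert s.site_class == "crest"
    assert abs(s.strain) < 4.0          # k_BT; small vs. |dG| = 8
    assert s.dE_total == pytest.approx(-8.0, abs=4.0)


def test_attempt_assembly_rules(params):
    rng = np.random.default_rng(0)
    positives = [AssemblySite(p, "crest", -8.0, 10.0, 2.0) for p in range(3)]
    assert attempt_assembly(positives, rng, params)[0] is None
    one = positives + [AssemblySite(7, "gap", -16.0, 1.0, -15.0)]
    chosen, prob, _ = attempt_assembly(one, rng, params)
    assert chosen.protofilament_index == 7
    assert prob == pytest.approx(1.0)


def test_attempt_assembly_equal_sites_are_uniform(params):
    """Two equal negative sites are chosen 50/50 (binomial 3-sigma)."""
    rng = np.random.default_rng(123)
    sites = [AssemblySite(0, "side", -12.0, 2.0, -10.0),
             AssemblySite(1, "side", -12.0, 2.0, -10.0)]
    n = 10_000
    picks = sum(attempt_assembly(sites, rng, params)[0].protofilament_index
                for _ in range(n))
    sigma = math.sqrt(n * 0.25)
    assert abs(picks - n / 2) < 3 * sigma


# ---------------------------------------------------------------------------
# hydrolysis
# ---------------------------------------------------------------------------

def big_sheet_lattice(n_per_pf=800):
    lat = Lattice(13, 3, wrap_seam=True)
    for p in range(13):
        for j in range(n_per_pf):
            lat.add_monomer(p, j, GTP)
    lat.zipped_count = 0   # everything above axial 3 counts as sheet
    return lat


def test_random_hydrolysis_threshold_one_never_fires():
    lat = big_sheet_lattice(50)
    rng = np.random.default_rng(1)
    n, draws = apply_hydrolysis(lat, "random", rng=rng, threshold=1.0)
    assert n == 0
    assert draws > 0
    assert not np.any(lat.nucleotide == GDP)


def test_random_hydrolysis_fraction_half():
    """At threshold 0.5 about half of ~1e4 tubulins hydrolyze."""
    lat = big_sheet_lattice(800)
    rng = np.random.default_rng(2)
    n, draws = apply_hydrolysis(lat, "random", rng=rng, threshold=0.5)
    assert draws >= 10_000
    sigma = math.sqrt(draws * 0.25)
    assert abs(n - draws / 2) < 3 * sigma


def test_random_hydrolysis_requires_valid_threshold():
    lat = big_sheet_lattice(10)
    with pytest.raises(ValueError):
        apply_hydrolysis(lat, "random", rng=np.random.default_rng(0),
                         threshold=1.5)


def test_hydrolysis_is_irreversible():
    lat = big_sheet_lattice(20)
    rng = np.random.default_rng(3)
    apply_hydrolysis(lat, "random", rng=rng, threshold=0.3)
    gdp_before = set(np.flatnonzero(lat.nucleotide == GDP).tolist())
    apply_hydrolysis(lat, "random", rng=rng, threshold=0.9)
    gdp_after = set(np.flatnonzero(lat.nucleotide == GDP).tolist())
    assert gdp_before <= gdp_after


def test_ordered_cap_keeps_top_layers():
    lat = big_sheet_lattice(20)
    apply_hydrolysis(lat, "ordered_cap", cap_layers=2)
    for g in range(lat.n_monomers):
        p, j = lat.loc(g)
        expected = GTP if j >= lat.pf_len(p) - 4 else GDP
        assert lat.nucleotide[g] == expected


# ---------------------------------------------------------------------------
# closure
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def closure_run():
    params = ModelParams()
    lat, conf = build_microtubule(params, 9, 4)
    model = EnergyModel(lat, params)
    relaxed, trace = relax(model, conf, params)
    zipped_before = lat.zipped_count
    gdp_before = int(np.sum(lat.nucleotide == GDP))
    conf2, res = close_monomer_pair(lat, relaxed, params,
                                    e_before=trace.final_energy)
    return {"params": params, "lat": lat, "res": res,
            "zipped_before": zipped_before, "gdp_before": gdp_before}


def test_closure_bookkeeping(closure_run):
    """One closure advances the zip front by one and adds exactly the
    lateral stretch/bend/dihedral terms of the new pair."""
    res = closure_run["res"]
    lat = closure_run["lat"]
    assert lat.zipped_count == closure_run["zipped_before"] + 1
    assert res.new_terms["stretch_lat"] == 1
    assert res.new_terms["bend_lat"] == 2
    assert res.new_terms["stretch_long"] == 0
    assert res.new_terms["stretch_diag"] == 0
    assert res.trace.converged


def test_closure_synchronous_hydrolysis_ring(closure_run):
    """The synchronous rule hydrolyzes one 13-tubulin ring per closure."""
    assert closure_run["res"].n_hydrolyzed == 13
    gdp_now = int(np.sum(closure_run["lat"].nucleotide == GDP))
    assert gdp_now == closure_run["gdp_before"] + 13


def test_closure_energetics_are_consistent(closure_run):
    res = closure_run["res"]
    params = closure_run["params"]
    assert res.barrier_kbt >= res.stepping_kbt > 0
    assert res.stepping_kbt == pytest.approx(
        (res.e_after - res.e_before) / params.kBT_internal)


def test_closure_on_blunt_tube_fails(params):
    lat, conf = build_microtubule(params, 12, 0)
    with pytest.raises(FullyZippedError):
        close_monomer_pair(lat, conf, params)


# ---------------------------------------------------------------------------
# event log determinism
# ---------------------------------------------------------------------------

def test_event_record_roundtrip():
    ev = EventRecord("closure", 4, {"pair_index": 9, "n_hydrolyzed": 13},
                     e_before=1.0, e_after=3.5, barrier=50.0)
    assert EventRecord.from_json(ev.to_json()) == ev


def test_assembly_selection_is_seed_deterministic(params):
    sites = [AssemblySite(p, "side", -12.0, float(p), -12.0 + p)
             for p in range(8)]
    picks1 = [attempt_assembly(sites, np.random.default_rng(99), params)[0]
              .protofilament_index for _ in range(5)]
    picks2 = [attempt_assembly(sites, np.random.default_rng(99), params)[0]
              .protofilament_index for _ in range(5)]
    assert picks1 == picks2
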