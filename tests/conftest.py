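import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mtsheet import ModelParams
from mtsheet.growth import (prepare_sheet_state, run_closure_sequence,
                            run_sensitivity_sweep)
from mtsheet.io import make_fixture, rng_streams


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def planar(params):
    return make_fixture("planar_3x4", params)


@pytest.fixture
def perturbed_planar(params, planar):
    """Planar fixture with a deterministic random displacement field."""
    lat, conf = planar
    rng = np.random.default_rng(7)
    conf.positions = conf.positions + rng.normal(0.0, 0.08,
                                                 conf.positions.shape)
    return lat, conf


@pytest.fixture(scope="session")
def standard_closures():
    """Three seam closures on the full standard configuration.

    The standard experiment: 30-monomer closed GDP body per protofilament
    plus the ten-monomer GTP sheet (520 monomers), form-found to its
    equilibrium, then three successive monomer-pair closures with
    synchronous hydrolysis.  Shared across the acceptance tests.
    """
    params = ModelParams()
    state = prepare_sheet_state(params)
    result, final = run_closure_sequence(params, 3, state=state)
    return {"params": params, "initial": state, "result": result,
            "final": final}


#: reduced problem size for the variant battery: 12-monomer body plus the
#: standard ten-monomer sheet; barrier/stepping are end-local quantities,
#: insensitive to body length
VARIANT_BODY = 12
VARIANT_SHEET = 10


@pytest.fixture(scope="session")
def variant_battery():
    """One closure per scenario variant (nucleotide states, curvature,
    random hydrolysis, constant scalings) at reduced body size."""
    p = ModelParams()

    def one(params, pattern="gtp", rule="synchronous_turn", rng=None):
        res, _ = run_closure_sequence(
            params, 1, body_monomers=VARIANT_BODY,
            sheet_monomers=VARIANT_SHEET, sheet_pattern=pattern,
            hydrolysis_rule=rule, rng=rng)
        return res.barriers[0], res.steppings[0]

    out = {}
    out["standard"] = one(p)
    out["curv0"] = one(p.copy(theta0_long_GTP=1e-3))
    out["curv15"] = one(p.copy(theta0_long_GTP=15.0))
    out["half_gdp"] = one(p, pattern="half_gdp")
    out["random"] = one(p, pattern="interlaced", rule="random",
                        rng=rng_streams(42)["hydrolysis"])
    for const, fac in [("k_lat_dihedral", 0.1), ("k_lat_dihedral", 10.0),
                       ("k_long_dihedral", 0.1), ("k_long_dihedral", 10.0),
                       ("k_diag_stretch", 0.1)]:
        res = run_sensitivity_sweep(p, const, [fac],
                                    body_monomers=VARIANT_BODY,
                                    sheet_monomers=VARIANT_SHEET)
        out[f"{const}x{fac}"] = (res.barriers[0], res.steppings[0])
    return out
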