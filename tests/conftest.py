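import numpy as np
import pytest

import crabipm as c


@pytest.fixture(scope="session")
def grid():
    return c.make_grid(0, 110, 5)


@pytest.fixture(scope="session")
def truth():
    return c.default_truth()


@pytest.fixture(scope="session")
def small_synth(truth):
    """One small synthetic study shared by read-only tests."""
    from crabipm.inference import D1Data

    design = c.TrappingDesign(n_years=3, traps_per_occasion=10)
    records, tr = c.generate_d1(truth, design, seed=11)
    d2, eps_u = c.generate_d2(truth, 100, [2000, 2001, 2002], seed=12)
    d3 = c.generate_d3(truth, 8, 120, 20, seed=13)
    d1 = D1Data.from_records(records, tr.grid, design.n_years,
                             tr.season.t_max)
    return {"records": records, "truth": tr, "d1": d1, "d2": d2, "d3": d3,
            "eps_u": eps_u, "design": design}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
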