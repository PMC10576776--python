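import numpy as np
import pandas as pd
import pytest

from somiteclock.synthetic import ClockSimParams, simulate_boundary_outcomes


@pytest.fixture(scope="session")
def default_sim():
    """A moderately sized simulated cohort shared across read-only tests."""
    params = ClockSimParams(n_embryos=200, seed=123)
    embryos, table = simulate_boundary_outcomes(params)
    return params, embryos, table


@pytest.fixture()
def tiny_table():
    """Hand-written 2-embryo boundary table over boundaries 11-14."""
    rows = []
    # e1: one defected boundary on the left, right all intact
    for b, ph in zip(range(11, 15), [0, 1, 0, 0]):
        rows.append(("e1", "L", b, ph, "ctrl"))
    for b in range(11, 15):
        rows.append(("e1", "R", b, 0, "ctrl"))
    # e2: all intact both sides
    for side in ("L", "R"):
        for b in range(11, 15):
            rows.append(("e2", side, b, 0, "ctrl"))
    return pd.DataFrame(
        rows, columns=["embryo_id", "side", "boundary_index", "phenotype", "condition"]
    )
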