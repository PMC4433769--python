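import numpy as np
import pytest

from scalemap.data import (
    Instrument,
    load_trials,
    social_anxiety_dataset,
    standardise_dataset,
)


@pytest.fixture(scope="session")
def anxiety():
    return social_anxiety_dataset()


@pytest.fixture(scope="session")
def anxiety_std(anxiety):
    return standardise_dataset(anxiety)


def make_rows(specs):
    """Rows for load_trials from compact (tid, arm, nc, na, instr, y, se, sd)."""
    return [
        {
            "trial_id": tid,
            "arm_index": arm,
            "n_control": nc,
            "n_arm": na,
            "instrument": ins,
            "mean_diff": y,
            "se": se,
            "pooled_sd": sd,
            "basis": "unknown",
        }
        for tid, arm, nc, na, ins, y, se, sd in specs
    ]


@pytest.fixture
def two_instrument_trial():
    """Two-arm trial reporting two instruments, Davidson (2004)-like numbers."""
    ds = load_trials(
        make_rows(
            [
                ("T1", 1, 126, 121, "A", -13.8, 3.05, 28.7),
                ("T1", 1, 126, 121, "B", -0.5, 0.14, 1.11),
            ]
        ),
        instruments=(Instrument("A"), Instrument("B")),
    )
    return ds.trials[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20150123)
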