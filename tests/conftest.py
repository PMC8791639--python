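import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from promotherm.model import EnergyModel
from promotherm.synthetic import make_truth_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_model():
    """Random sigma70-like model with the default 24-contact geometry."""
    return make_truth_model(seed=1, mu=-5.0)


@pytest.fixture
def compact_model():
    """Small-footprint model for cheap exhaustive checks."""
    return make_truth_model(seed=2, l35=6, l10=6, optimal_spacer=9,
                            spacer_flex=1, mu=-3.0)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def random_seq_factory(rng):
    return lambda length: random_seq(rng, length)


def consensus_sequence(model: EnergyModel, spacer: int | None = None,
                       rng=None) -> str:
    """Minimum-energy sequence for a model at a given spacer length."""
    if spacer is None:
        spacer = model.optimal_spacer
    if rng is None:
        rng = np.random.default_rng(0)
    cons = model.contact_matrix().argmin(axis=0)
    mid = rng.integers(0, 4, size=spacer)
    idx = list(cons[:model.l35]) + list(mid) + list(cons[model.l35:])
    return "".join("ACGT"[i] for i in idx)
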