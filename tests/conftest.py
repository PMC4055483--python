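import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from psesplice import Label, LabeledDataset, SiteType, SpliceSequence
from psesplice.synthetic import SimConfig, simulate


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def tiny_donor_dataset():
    """Three labeled 140-nt donor windows with GT at positions 70-71."""
    rng = np.random.default_rng(7)
    seqs = []
    for i, label in enumerate([Label.TRUE_SITE, Label.TRUE_SITE, Label.FALSE_SITE]):
        s = list(random_sequence(rng, 140))
        s[69], s[70] = "G", "T"
        seqs.append(SpliceSequence(f"d{i}", "".join(s), SiteType.DONOR, label))
    return LabeledDataset(seqs, SiteType.DONOR)


@pytest.fixture
def separable_dataset():
    """Small strongly-separable synthetic donor benchmark."""
    ds, _ = simulate(
        SimConfig(n_pos=25, n_neg=25, site_type="donor", consensus_strength=1.0, seed=11)
    )
    return ds


@pytest.fixture
def null_dataset():
    """Small zero-signal synthetic donor benchmark."""
    ds, _ = simulate(
        SimConfig(n_pos=25, n_neg=25, site_type="donor", consensus_strength=0.0, seed=12)
    )
    return ds
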