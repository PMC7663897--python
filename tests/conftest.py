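import numpy as np
import pytest

from triplexpot.features import fit_class_means
from triplexpot.io import Dataset, SequenceRecord
from triplexpot.simulate import CompositionSpec, SyntheticDesign, generate


def make_record(rid, seq, **kw):
    return SequenceRecord(id=rid, seq=seq, **kw)


def random_dataset(n, length, probs, seed, label=None, subtype=None, prefix="r"):
    """i.i.d. sequences from a base composition."""
    rng = np.random.default_rng(seed)
    recs = [
        SequenceRecord(
            id=f"{prefix}{i}",
            seq="".join(rng.choice(list("ACGT"), size=length, p=probs)),
            label=label,
            subtype=subtype,
        )
        for i in range(n)
    ]
    return Dataset(recs)


@pytest.fixture
def tiny_pos():
    return random_dataset(12, 60, (0.1, 0.4, 0.4, 0.1), seed=1, label="positive",
                          prefix="p")


@pytest.fixture
def tiny_neg():
    return random_dataset(12, 60, (0.4, 0.1, 0.1, 0.4), seed=2, label="negative",
                          prefix="n")


@pytest.fixture
def tiny_profile(tiny_pos, tiny_neg):
    return fit_class_means(tiny_pos, tiny_neg)


@pytest.fixture
def small_design():
    """Small but non-trivial synthetic design shared by pipeline tests."""
    return SyntheticDesign(
        pos_strong=CompositionSpec("pos_strong", (0.1, 0.4, 0.4, 0.1), (100, 300)),
        pos_weak=CompositionSpec("pos_weak", (0.3, 0.2, 0.2, 0.3), (100, 300)),
        neg=CompositionSpec("neg", (0.4, 0.1, 0.1, 0.4), (100, 300)),
        n_pos_strong=20,
        n_pos_weak=8,
        n_neg=80,
        seed=11,
    )


@pytest.fixture
def small_data(small_design):
    return generate(small_design)
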