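import numpy as np
import pytest

from closematch import BarcodeLibrary, SimParams, simulate_library


@pytest.fixture
def toylib1():
    """4 sequences, 2 species; Beta is a singleton."""
    return BarcodeLibrary.from_sequences(
        ["Alpha_1", "Alpha_2", "Alpha_3", "Beta_1"],
        ["Alpha", "Alpha", "Alpha", "Beta"],
        ["ACGT", "ACGT", "ACGA", "TTTT"],
    )


@pytest.fixture
def toylib2():
    """Ambiguity fixture: Alpha_2 ties with one conspecific and one allospecific."""
    return BarcodeLibrary.from_sequences(
        ["Alpha_1", "Beta_1", "Alpha_2"],
        ["Alpha", "Beta", "Alpha"],
        ["AAAA", "AAAA", "AAAT"],
    )


@pytest.fixture
def random_library():
    """Factory for small simulated libraries with varied parameters."""

    def make(seed, **overrides):
        rng = np.random.default_rng(seed)
        params = dict(
            n_species=int(rng.integers(2, 8)),
            seqs_per_species=(1, 4),
            alignment_length=int(rng.integers(60, 140)),
            intra_p=float(rng.uniform(0.0, 0.05)),
            inter_p=float(rng.uniform(0.08, 0.5)),
            missing_species_fraction=float(rng.uniform(0.0, 0.5)),
            n_rate=float(rng.choice([0.0, 0.02, 0.1])),
            seed=seed,
        )
        params.update(overrides)
        return simulate_library(SimParams(**params))

    return make
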