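import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ncminer.chem_io import CompoundRecord, FingerprintSpec, InteractionDataset
from ncminer.snn_core import SiameseModel
from ncminer.synth_data import SynthSpec, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

N_BITS_SMALL = 64


def make_dataset(rows, n_bits=N_BITS_SMALL, seed=0, fingerprints=None):
    """Hand-built dataset from (compound_id, protein_id, active) triples."""
    rng = np.random.default_rng(seed)
    cids = list(dict.fromkeys(r[0] for r in rows))
    fingerprints = fingerprints or {}
    compounds = {
        c: CompoundRecord(
            c, fingerprints.get(c, (rng.random(n_bits) < 0.3).astype(np.uint8))
        )
        for c in cids
    }
    inter = pd.DataFrame(rows, columns=["compound_id", "protein_id", "active"])
    return InteractionDataset(
        compounds=compounds,
        interactions=inter,
        fingerprint_spec=FingerprintSpec.synthetic(n_bits),
    )


@pytest.fixture
def toy_ds():
    """3 proteins; c1 is dual-active (P1, P2); c5/c6 are inactives."""
    return make_dataset(
        [
            ("c1", "P1", True),
            ("c1", "P2", True),
            ("c2", "P1", True),
            ("c3", "P2", True),
            ("c4", "P3", True),
            ("c7", "P3", True),
            ("c5", "P1", False),
            ("c6", "P3", False),
        ]
    )


@pytest.fixture
def clustered_ds():
    """Two well-separated synthetic clusters (small fingerprints, low noise)."""
    return generate_dataset(
        SynthSpec(
            n_proteins=2, actives_per_protein=30, inactives_per_protein=15,
            fingerprint_length=N_BITS_SMALL, flip_rate=0.02, seed=7,
        )
    )


@pytest.fixture
def small_model():
    """Untrained model sized for the 64-bit synthetic fingerprints."""
    return SiameseModel.create(
        FingerprintSpec.synthetic(N_BITS_SMALL), hidden_dims=(32, 16), seed=3
    )
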