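import numpy as np
import pytest

from ampcore import synthetic
from ampcore.features import FeatureTracks


def make_random_tracks(n: int, rng: np.random.Generator, seq_id: str = "t") -> FeatureTracks:
    """Random but internally consistent feature tracks for CRF tests."""
    channels = {
        "PRIMARY": tuple(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n)),
        "SS": tuple(rng.choice(list("HEC"), n)),
        "DOMAIN": tuple(rng.choice(["IN", "OUT"], n)),
        "ALIGN": tuple(rng.choice(["IN", "OUT"], n)),
        "AMPA": tuple(rng.choice(["IN", "OUT"], n)),
        "AGGR": tuple(rng.choice(["IN", "OUT"], n)),
        "CHARGE": tuple(rng.choice(["LEADING", "POSITIVE", "NONPOSITIVE"], n)),
        "AMPH": tuple(rng.choice(["IN", "OUT"], n)),
    }
    return FeatureTracks(sequence_id=seq_id, length=n, channels=channels)


@pytest.fixture(scope="session")
def small_corpus():
    """30 featurized synthetic families, shared across tests."""
    cfg = synthetic.SimConfig(n_families=30, seed=11)
    return synthetic.generate_dataset(cfg)
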