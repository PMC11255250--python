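import numpy as np
import pytest

from tcnss import synthetic, workflow
from tcnss.featurize import PhysChemTable


@pytest.fixture(scope="session")
def physchem_table() -> PhysChemTable:
    return PhysChemTable.default()


@pytest.fixture(scope="session")
def tiny_cfg() -> workflow.ModelConfig:
    """Very small model for fast structural tests."""
    return workflow.desk_scale_config(
        tcn_channels=4, tcn_width=8, lstm_hidden=4, attention_width=8,
        classifier_width=8, embedding_dim=4, embedding_epochs=1,
        epochs=2, scales=(1, 3), seed=0)


@pytest.fixture(scope="session")
def easy_records():
    """Deterministic-emission corpus: labels are a function of residues."""
    return synthetic.generate(synthetic.easy_preset(n_records=8, length=30,
                                                    seed=3))


def random_labels(rng: np.random.Generator, alphabet: str, length: int) -> str:
    """Random label string with geometric run lengths (mean 3)."""
    out = []
    while len(out) < length:
        state = alphabet[rng.integers(len(alphabet))]
        out.extend(state * int(rng.geometric(1 / 3.0)))
    return "".join(out[:length])
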