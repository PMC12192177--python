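import numpy as np
import pytest

from oxipept import (
    LabeledDataset,
    PeptideRecord,
    ResourceBundle,
    SynthesisConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def bundle() -> ResourceBundle:
    return ResourceBundle.default()


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """60 peptides with strong composition signal; cheap to encode."""
    cfg = SynthesisConfig(n_pos=30, n_neg=30, enrichment=6.0,
                          length_range=(10, 30), seed=42)
    return generate_dataset(cfg)


@pytest.fixture()
def toy_separable():
    """Linearly separable 2-feature toy set."""
    rng = np.random.default_rng(0)
    X0 = rng.normal(loc=-2.0, scale=0.3, size=(20, 2))
    X1 = rng.normal(loc=+2.0, scale=0.3, size=(20, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 20 + [1] * 20)
    return X, y


@pytest.fixture()
def peptide():
    return PeptideRecord("pep1", "GSHWY")
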