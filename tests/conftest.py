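import numpy as np
import pandas as pd
import pytest

from netpharm import synthetic


@pytest.fixture(scope="session")
def small_itraq():
    """Small planted 4-plex dataset shared across tests (fast to generate)."""
    cfg = synthetic.ItraqSimConfig(
        n_proteins=60, frac_up=0.1, frac_down=0.1, seed=11
    )
    spectra, truth = synthetic.gen_itraq_dataset(cfg)
    return cfg, spectra, truth


@pytest.fixture()
def toy_spectra():
    """Three-peptide, one-protein, one-batch spectra table with exact ratios."""
    return pd.DataFrame(
        {
            "peptide_id": ["pep1", "pep2", "pep3"],
            "protein_acc": ["P1"] * 3,
            "batch": [1, 1, 1],
            "area_114": [100.0, 200.0, 50.0],
            "area_115": [200.0, 600.0, 25.0],
            "area_116": [100.0, 200.0, 50.0],
            "area_117": [50.0, 100.0, 100.0],
            "protein_score": [10.0] * 3,
            "unused_score": [5.0] * 3,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
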