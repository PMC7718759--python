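import numpy as np
import pandas as pd
import pytest

from chemscreen import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_screen():
    """One-plate synthetic screen with planted sensitive/resistant/dead strains."""
    cfg = simulate.ColonyScreenConfig(
        n_strains=300,
        frac_sensitive=10 / 300,
        frac_resistant=2 / 300,
        frac_dead=10 / 300,
    )
    pairs, truth = simulate.simulate_colony_screen(cfg, seed=11)
    return cfg, pairs, truth


def annotations_for(truth: pd.DataFrame, filler: str = "border_control") -> pd.DataFrame:
    """1:1 strain->gene annotation table for a synthetic truth table."""
    ann = pd.DataFrame(
        {
            "strain": truth["strain_id"],
            "gene": truth["strain_id"],
            "allele": truth["strain_id"],
            "collection": "deletion",
            "essential": False,
            "category": "",
        }
    )
    filler_row = pd.DataFrame(
        {
            "strain": [filler],
            "gene": [filler],
            "allele": [filler],
            "collection": ["deletion"],
            "essential": [False],
            "category": [""],
        }
    )
    return pd.concat([ann, filler_row], ignore_index=True)
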