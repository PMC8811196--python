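import numpy as np
import pandas as pd
import pytest

from doclinker.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SyntheticConfig(
        n_samples=30,
        n_otus_bacteria=60,
        n_otus_fungi=20,
        n_planted_positive=2,
        n_planted_negative=2,
        library_size_range=(2500, 4000),
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_taxonomy():
    """Hand-built taxonomy covering every confidence-filter case."""
    ranks = ["kingdom", "phylum", "class", "order", "family", "genus"]
    rows = {
        # all ranks confident
        "OTU_good": dict(zip(ranks, ["Bacteria", "P", "C", "O", "F", "G"])),
        # kingdom below 100 -> removed
        "OTU_badking": dict(zip(ranks, ["Bacteria", "P", "C", "O", "F", "G"])),
        # phylum below 80 -> removed
        "OTU_badphy": dict(zip(ranks, ["Bacteria", "P", "C", "O", "F", "G"])),
        # genus 67 / family 90 -> effective rank family
        "OTU_fam": dict(zip(ranks, ["Bacteria", "P", "C", "O", "F", "G"])),
    }
    df = pd.DataFrame(rows).T
    conf = {
        "OTU_good": [100, 95, 90, 88, 90, 85],
        "OTU_badking": [99, 95, 90, 88, 90, 85],
        "OTU_badphy": [100, 79, 90, 88, 90, 85],
        "OTU_fam": [100, 80, 88, 90, 90, 67],
    }
    for i, r in enumerate(ranks):
        df[f"{r}_conf"] = [conf[o][i] for o in df.index]
    return df
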