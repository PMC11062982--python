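import numpy as np
import pandas as pd
import pytest

from azoreg import simulate as sim


@pytest.fixture(scope="session")
def small_compendium():
    """A reduced compendium (8 datasets, 300 genes) with one planted module."""
    cfg = sim.CompendiumSimConfig(
        n_datasets=8,
        n_genes=300,
        samples_per_dataset=(6, 10),
        total_samples=None,
        planted_modules=(sim.PlantedModule(("tesA", "pspE", "nfsA"), 0.95, 6),),
        seed=123,
    )
    return sim.gen_compendium(cfg)


@pytest.fixture(scope="session")
def small_screen():
    cfg = sim.ScreenSimConfig(n_mutants=460, seed=77)
    plates, truth = sim.gen_screen(cfg)
    return cfg, plates, truth


@pytest.fixture
def ct_table():
    """Deterministic two-condition Ct table with a clean 4-fold induction."""
    rows = []
    for rep in (1, 2, 3):
        rows += [
            ("azoR", "treated", rep, 20.0),
            ("azoR", "control", rep, 22.0),
            ("ihfB", "treated", rep, 15.0),
            ("ihfB", "control", rep, 15.0),
        ]
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
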