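import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import mirmeta as M


@pytest.fixture(scope="session")
def small_dataset():
    """Three blood studies (2 array + 1 rnaseq), mixed planted effects."""
    cfg = M.SimulationConfig(
        n_studies=3,
        platform_per_study=["array", "array", "rnaseq"],
        tissue_per_study=["blood"] * 3,
        n_mirnas=120,
        frac_shared=0.1,
        frac_female_only=0.05,
        frac_male_only=0.05,
        mu_shared=1.5,
        mu_female_only=1.5,
        mu_male_only=1.5,
        seed=42,
    )
    bundles, truth = M.simulate_multistudy(cfg)
    return cfg, bundles, truth


@pytest.fixture(scope="session")
def small_meta(small_dataset):
    cfg, bundles, truth = small_dataset
    de = [r for b in bundles for r in M.run_de(b)]
    meta = M.run_meta(de, strata=(("blood", "female"), ("blood", "male")))
    return de, meta, truth
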