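import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from budtraj.synthetic import TruthSpec, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_ds():
    """Reference-scale noisy dataset with the full default planted
    structure (800 genes, 36 samples)."""
    return generate_dataset(TruthSpec(n_genes=800, seed=11))


@pytest.fixture(scope="session")
def clean_ds():
    """Fully deterministic dataset: no replicate noise, no latent factors,
    no planted divergence, expression high enough that no TPM clips at 0 —
    every downstream statistic has a closed form here."""
    spec = TruthSpec(n_genes=320, noise_sd=0.0, coexpr_blocks=(),
                     divergent_modules={}, gene_mean_loc=8.0,
                     gene_mean_scale=0.5, baseline_sd=0.8,
                     cultivar_jitter_sd=0.2, seed=7)
    ds = generate_dataset(spec)
    assert (ds.expression.values.to_numpy() > 0).all()
    return ds


@pytest.fixture(scope="session")
def design36(ref_ds):
    return ref_ds.expression.design


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_design(cultivars=(("A", "Low"), ("B", "High")), stages=("S1", "S2"),
               reps=1):
    rows = [{"sample_id": f"{c}_{s}_r{r}", "cultivar": c, "stage": s,
             "replicate": r, "cr_group": g}
            for c, g in cultivars for s in stages for r in range(1, reps + 1)]
    return pd.DataFrame(rows)
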