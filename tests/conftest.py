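import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from regdecomp import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Study conditions of the whole-testis design: 3 replicates/genotype,
#: NB dispersion 0.05, baseline 256 normalized counts (log2 = 8).
STUDY_KW = dict(
    n_replicates=3, baseline_log2_mean_range=(8.0, 8.0), dispersion=0.05
)


@pytest.fixture(scope="session")
def mixed_experiment():
    """Five-genotype simulation with 100 genes per category I-V,
    |effect| = 2 log2 units, under the study conditions."""
    arch = sd.architecture_from_counts(
        {"I": 100, "II": 100, "III": 100, "IV": 100, "V": 100},
        effect=2.0,
        rng=np.random.default_rng(5),
    )
    cfg = sd.SimConfig(n_genes=500, effect_arch=arch, seed=42, **STUDY_KW)
    return sd.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def null_experiment():
    """Global-null simulation: no effects, no context shift."""
    cfg = sd.SimConfig(n_genes=2000, seed=42, **STUDY_KW)
    return sd.simulate_experiment(cfg)


def make_contrast_table(A, B, C, se=0.3, n=3, ok=True):
    """Hand-built one-gene contrast table for classification tests.

    Per-group variance components are split evenly so that the
    shared-baseline B vs C test sees se^2 = (se_B^2 + se_C^2) / 2.
    """
    row = {}
    for name, lfc in zip("ABC", (A, B, C)):
        row[name] = lfc
        row[f"{name}_se"] = se
        row[f"{name}_v1"] = se**2 / 2
        row[f"{name}_v2"] = se**2 / 2
        row[f"{name}_n1"] = n
        row[f"{name}_n2"] = n
        row[f"{name}_ok"] = ok
    return pd.DataFrame([row], index=["gene"])
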