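import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crcmark.config import CohortConfig
from crcmark.io import serum_levels_from_samples
from crcmark.qpcr import process_table
from crcmark.synthetic import generate_cohort, generate_ct_table

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded 85-patient cohort (57 radical / 28 palliative)."""
    cfg = CohortConfig(seed=20190621)
    clinical, samples = generate_cohort(cfg)
    return cfg, clinical, samples


@pytest.fixture(scope="session")
def processed_levels(default_cohort):
    """Levels table produced by the full qPCR chain plus serum markers."""
    cfg, clinical, samples = default_cohort
    raw = generate_ct_table(samples, cfg)
    levels, log = process_table(raw)
    levels = pd.concat([levels, serum_levels_from_samples(samples)], ignore_index=True)
    return clinical, samples, levels, log


def true_levels_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Treat generator truth as a qc-ok level table (bypasses the Ct chain)."""
    out = samples.copy()
    out["qc_flag"] = "ok"
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
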