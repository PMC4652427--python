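import numpy as np
import pandas as pd
import pytest

from cogchange import generate_cohort, reference_config


def make_cohort_df(rows):
    """Build a minimal valid cohort frame from (id, group, age, edu, gender) tuples."""
    base = pd.DataFrame(
        rows, columns=["subject_id", "group", "age", "education_years", "gender"]
    )
    for name, lo in (("AQ", 5), ("FAQ", 3), ("MMSE", 25)):
        base[f"{name}_y1"] = lo
        base[f"{name}_y2"] = lo + 1
    for scale, cat in (("FAST", 2.0), ("GDS", 2.0), ("CDR", 0.0)):
        base[f"{scale}_y1"] = cat
        base[f"{scale}_y2"] = cat
    return base


@pytest.fixture(scope="session")
def ref_cohort():
    """A reference-calibrated synthetic cohort at the study's group sizes."""
    return generate_cohort(reference_config(seed=202))


@pytest.fixture(scope="session")
def big_cohort():
    """Discretized cohort with 10,000 subjects per group (moment checks)."""
    cfg = reference_config(
        n_per_group={"CN": 10_000, "aMCI": 10_000, "AD": 10_000}, seed=11
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_latent_cohort():
    """Latent-normal cohort with 10,000 subjects per group (exact-model checks)."""
    cfg = reference_config(
        n_per_group={"CN": 10_000, "aMCI": 10_000, "AD": 10_000}, seed=11
    )
    return cfg, generate_cohort(cfg, latent=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
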