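import numpy as np
import pandas as pd
import pytest

from pkmetab import synth
from pkmetab.feature_qc import FeatureTable


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject low-noise cohort with its generating truth."""
    spec = synth.CohortSpec(n_subjects=8, assay_noise_cv=0.02, seed=31)
    return synth.simulate_pk_profiles(spec)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    """Feature table for the small cohort, with planted/bad features."""
    _, truth = small_cohort
    link = synth.FeatureLinkSpec(
        n_features=120, n_planted=6, n_unstable=15, n_nondiluting=10,
        n_qc_pools=6, seed=32,
    )
    return synth.simulate_feature_table(link, truth)


def toy_table(abundance, roles, dilution_factors=None, is_feature_id=None):
    """Hand-built FeatureTable from a plain dict of feature -> values."""
    df = pd.DataFrame(abundance, dtype=float)
    df.index = [f"s{i}" for i in range(len(df))]
    manifest = pd.DataFrame(
        {
            "role": roles,
            "dilution_factor": dilution_factors or [np.nan] * len(df),
            "order": range(len(df)),
        },
        index=df.index,
    )
    metadata = pd.DataFrame(
        {"rt_min": 1.0, "mz": 100.0, "mode": "positive"}, index=df.columns
    )
    return FeatureTable(
        abundance=df,
        sample_manifest=manifest,
        feature_metadata=metadata,
        is_feature_id=is_feature_id,
    )
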