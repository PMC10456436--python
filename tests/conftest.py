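import numpy as np
import pandas as pd
import pytest

from serdakit import FeatureTable, SyntheticConfig, simulate_study


def make_table(
    intensities,
    roles,
    batches=None,
    compound_meta=None,
    istd_map=None,
    replicate_groups=None,
):
    """Hand-built FeatureTable with sequential injection order."""
    x = np.asarray(intensities, dtype=float)
    n, d = x.shape
    samples = pd.DataFrame(
        {
            "injection_order": np.arange(1, n + 1),
            "batch": batches if batches is not None else ["B1"] * n,
            "role": roles,
            "replicate_group": replicate_groups
            if replicate_groups is not None
            else [None] * n,
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"),
    )
    compounds = pd.DataFrame(
        index=pd.Index([f"C{j}" for j in range(d)], name="compound_id")
    )
    compounds["is_identified"] = True
    compounds["is_istd"] = False
    compounds["is_fame"] = False
    if compound_meta:
        for col, vals in compound_meta.items():
            compounds[col] = vals
    return FeatureTable(
        intensities=x,
        samples=samples,
        compounds=compounds,
        istd_map=istd_map or {},
    )


@pytest.fixture(scope="session")
def small_drifted():
    """Small drifted acquisition shared by the slower unit tests."""
    cfg = SyntheticConfig(
        d=40, n_study=200, n_batches=3, replicate_pairs=3, seed=42
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full default acquisition (shared with acceptance-scale checks)."""
    return simulate_study(SyntheticConfig(seed=1))
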