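import pandas as pd
import pytest

import metabosubtype as ms


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with strong planted signal, shared across tests."""
    cfg = ms.SyntheticConfig(n_samples=150, n_genes=80, n_prognostic=5,
                             effect_size=1.0, subtype_shift=2.0, seed=11)
    expr, clin, truth = ms.generate_cohort(cfg)
    return cfg, expr, clin, truth


@pytest.fixture(scope="session")
def small_zscores(small_cohort):
    _, expr, clin, _ = small_cohort
    norm, _ = ms.median_of_ratios_normalize(expr)
    return ms.zscore_genes(ms.log_transform(norm)), clin


def toy_clinical(times, events, ids=None, **covs):
    ids = ids or [f"P{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events, **covs},
                      index=pd.Index(ids, name="sample_id"))
    return ms.ClinicalTable(df)


def random_counts(rng, n_genes=50, n_samples=6, low=1, high=400):
    vals = rng.integers(low, high, size=(n_genes, n_samples))
    return ms.ExpressionMatrix(
        pd.DataFrame(vals,
                     index=[f"G{i}" for i in range(n_genes)],
                     columns=[f"S{j}" for j in range(n_samples)]),
        mode="counts")
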