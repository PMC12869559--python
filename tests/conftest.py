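import numpy as np
import pandas as pd
import pytest

from cardiocc.models import DiseaseModel
from cardiocc.simulate import default_config, simulate_paired_sumstats
from cardiocc.sumstats import SumstatsTable


@pytest.fixture(scope="session")
def study_conditions():
    """The study-mirroring configuration at the package's desk scale."""
    return default_config(seed=7)


@pytest.fixture(scope="session")
def paired_sim(study_conditions):
    """One paired simulation shared by read-only tests."""
    a, b, truth = simulate_paired_sumstats(study_conditions)
    return a, b, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small, well-powered pair for fast structural tests."""
    cfg = default_config(m_variants=5_000, m_causal=400, seed=11)
    a, b, truth = simulate_paired_sumstats(cfg)
    return a, b, truth


def make_table(
    label="toy",
    chrom=None,
    pos=None,
    ea=None,
    oa=None,
    eaf=None,
    beta=None,
    se=None,
    n_case=None,
    n_control=None,
    n=None,
):
    """Hand-built canonical table for unit tests."""
    m = len(beta)
    from scipy import stats

    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    z = beta / se
    df = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (1 + np.arange(m) * 1000),
            "effect_allele": ea if ea is not None else ["A"] * m,
            "other_allele": oa if oa is not None else ["G"] * m,
            "eaf": eaf if eaf is not None else [0.5] * m,
            "beta": beta,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "z": z,
            "n_case": n_case,
            "n_control": n_control,
            "n": n,
        }
    )
    return SumstatsTable(label, df)


@pytest.fixture
def toy_diseases():
    a = DiseaseModel("A", 0.004, 0.142, 9_365, 1_199_156)
    b = DiseaseModel("B", 0.002, 0.180, 5_900, 68_359)
    return a, b
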