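"""Shared helpers for the numbered analysis drivers.

Every driver regenerates the study-condition synthetic data from one seed (the
generation is cheap), so the scripts can be run independently and in any
order; `01_simulate_sumstats.py` additionally writes the datasets to disk for
the record.
"""

from pathlib import Path

from cardiocc.casecase import casecase_stats
from cardiocc.models import CrossTraitModel
from cardiocc.simulate import (
    default_config,
    simulate_endophenotype,
    simulate_paired_sumstats,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def study_data(seed: int = SEED):
    """Paired disease scans, endophenotypes and ground truth."""
    cfg = default_config(seed=seed)
    a, b, truth = simulate_paired_sumstats(cfg)
    endos = [
        simulate_endophenotype(truth, label, h2, r)
        for label, h2, r in cfg.endophenotypes
    ]
    return cfg, a, b, truth, endos


def casecase_scan(cfg, a, b, truth, error_covariance=None):
    x = CrossTraitModel(
        rg=cfg.rg,
        m_causal=cfg.m_causal,
        error_covariance=truth.overlap_corr
        if error_covariance is None
        else error_covariance,
    )
    return casecase_stats(a, b, cfg.disease_a, cfg.disease_b, x)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
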