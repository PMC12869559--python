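"""Case-case association statistics reconstructed from two case-control scans.

Effects are moved from the per-allele log-odds scale to the *delta scale*: the
standardized mean-genotype deviation of cases from the population,
delta = beta * sqrt(2 p (1-p)) * (1 - K) under the small-effect liability
approximation.  The case-case contrast (A-cases vs B-cases) is then

    ordinary:  delta_hat_A - delta_hat_B
    exact:     w_A delta_hat_A - w_B delta_hat_B,   w_i = sqrt(s_A s_B) / s_i

with s_i = phi(tau_i)/K_i the liability-to-delta scale factor of disorder i.
The exact weights are constructed so that a variant with *equal liability-scale
(log-odds) effects* in both disorders has expectation exactly zero: such
"stress" variants are not case-case signal but acquire unequal delta effects
whenever the two prevalences differ, which inflates the ordinary statistic at
large sample sizes.  The geometric-mean normalization makes the two paths
coincide when s_A = s_B.

The genetic distance F_ST,causal — the expected squared standardized
case-group allele-frequency difference per causal variant — is

    (h2d_A + h2d_B - 2 rg sqrt(h2d_A h2d_B)) / m_causal

with h2d_i = h2_liability,i * (phi(tau_i)/K_i)^2 the delta-scale heritability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .models import CrossTraitModel, DiseaseModel, h2_liability_to_delta
from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

__all__ = ["to_delta_scale", "fst_causal", "casecase_stats"]

GENOME_WIDE_P = 5e-8


def to_delta_scale(
    table: SumstatsTable, disease: DiseaseModel
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Convert per-allele log-odds effects to the delta scale.

    Returns (delta, var_delta, metadata).  Variants with eaf at 0 or 1 are
    returned as NaN (skipped downstream) and counted in the metadata.
    """
    df = table.df
    p = df["eaf"].to_numpy(dtype=float)
    beta = df["beta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    bad = (p <= 0.0) | (p >= 1.0)
    if bad.any():
        logger.info(
            "to_delta_scale(%s): skipped %d variants with boundary eaf",
            table.trait_label,
            int(bad.sum()),
        )
    gvar = np.where(bad, np.nan, 2.0 * p * (1.0 - p))
    k = disease.prevalence
    delta = beta * np.sqrt(gvar) * (1.0 - k)
    var_delta = se**2 * gvar * (1.0 - k) ** 2
    meta = {
        "scale": "standardized case-vs-population allele-frequency difference",
        "prevalence": k,
        "one_minus_k": 1.0 - k,
        "n_skipped_boundary_eaf": int(bad.sum()),
    }
    return delta, var_delta, meta


def fst_causal(
    a: DiseaseModel, b: DiseaseModel, x: CrossTraitModel
) -> float:
    """Expected squared standardized case-group frequency difference per causal variant."""
    if not -1.0 <= x.rg <= 1.0:
        raise ValueError(f"rg must be in [-1,1], got {x.rg}")
    h2d_a = h2_liability_to_delta(a.h2_liability, a.prevalence)
    h2d_b = h2_liability_to_delta(b.h2_liability, b.prevalence)
    return float(
        (h2d_a + h2d_b - 2.0 * x.rg * np.sqrt(h2d_a * h2d_b)) / x.m_causal
    )


def casecase_stats(
    a: SumstatsTable,
    b: SumstatsTable,
    disease_a: DiseaseModel,
    disease_b: DiseaseModel,
    x: CrossTraitModel,
    attenuation: float = 1.0,
    sig_threshold: float = GENOME_WIDE_P,
) -> SumstatsTable:
    """Reconstruct case-case (A-cases vs B-cases) statistics from the pair.

    Both the ordinary (plain delta difference) and exact (stress-protected
    weighting) paths are emitted side by side; ``flag_stress`` marks variants
    where the ordinary path is genome-wide significant but the exact path is
    not.  ``attenuation`` scales both effective sample sizes for potential
    missingness (recorded in metadata, default 1.0).  If the overlap parameter
    (error covariance) is NaN the exact path is still computed but the overlap
    term is dropped from both variances, with a warning.
    """
    if len(a) != len(b):
        raise ValueError("tables must be harmonized before casecase_stats")
    ec = x.error_covariance
    if ec is None or np.isnan(ec):
        logger.warning("missing overlap parameter; assuming zero error covariance")
        ec = 0.0

    delta_a, var_a, meta_a = to_delta_scale(a, disease_a)
    delta_b, var_b, meta_b = to_delta_scale(b, disease_b)
    var_a = var_a / attenuation
    var_b = var_b / attenuation

    cov = ec * np.sqrt(var_a * var_b)

    d_ols = delta_a - delta_b
    v_ols = var_a + var_b - 2.0 * cov

    s_a = disease_a.case_scale
    s_b = disease_b.case_scale
    g = np.sqrt(s_a * s_b)
    w_a, w_b = g / s_a, g / s_b
    d_exact = w_a * delta_a - w_b * delta_b
    v_exact = w_a**2 * var_a + w_b**2 * var_b - 2.0 * w_a * w_b * cov

    with np.errstate(invalid="ignore", divide="ignore"):
        z_ols = d_ols / np.sqrt(v_ols)
        z_exact = d_exact / np.sqrt(v_exact)
    p_ols = 2.0 * stats.norm.sf(np.abs(z_ols))
    p_exact = 2.0 * stats.norm.sf(np.abs(z_exact))

    out = a.df[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
    ].copy()
    out["delta_ols"] = d_ols
    out["se_ols"] = np.sqrt(v_ols)
    out["z_ols"] = z_ols
    out["p_ols"] = p_ols
    out["delta_exact"] = d_exact
    out["se_exact"] = np.sqrt(v_exact)
    out["z_exact"] = z_exact
    out["p_exact"] = p_exact
    out["flag_stress"] = (p_ols < sig_threshold) & ~(p_exact < sig_threshold)

    # canonical columns so downstream stages (MTAG, loci) can consume the
    # exact path directly; the delta scale is carried in beta/se
    out["beta"] = d_exact
    out["se"] = out["se_exact"]
    out["z"] = z_exact
    out["p"] = p_exact
    n_cc = attenuation * (disease_a.n_case + disease_b.n_case)
    out["n_case"] = attenuation * disease_a.n_case
    out["n_control"] = attenuation * disease_b.n_case
    out["n"] = n_cc

    meta = {
        "method": "case-case reconstruction",
        "default_path": "exact",
        "prevalence_a": disease_a.prevalence,
        "prevalence_b": disease_b.prevalence,
        "h2_liability_a": disease_a.h2_liability,
        "h2_liability_b": disease_b.h2_liability,
        "rg": x.rg,
        "error_covariance": ec,
        "m_causal": x.m_causal,
        "fst_causal": x.fst_causal
        if x.fst_causal is not None
        else fst_causal(disease_a, disease_b, x),
        "attenuation": attenuation,
        "weights_exact": {"w_a": float(w_a), "w_b": float(w_b)},
        "delta_conversion_a": meta_a,
        "delta_conversion_b": meta_b,
        "sig_threshold": sig_threshold,
    }
    return SumstatsTable(
        f"{disease_a.label}_vs_{disease_b.label}", out, meta
    )
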