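"""Two-stage shared-effect meta-analysis of the disease pair.

Stage 1 is a plain fixed-effects inverse-variance-weighted combination after a
precision filter that removes variants whose standard errors differ grossly
between the two scans (robust MAD rule on the per-variant log SE ratio).
Stage 2 substitutes, for every variant with fixed-effects P below a trigger
threshold (default 1e-4), the two-study DerSimonian-Laird random-effects
P-value whenever it is more conservative: p_final = max(p_fe, p_re) for
triggered variants, p_fe otherwise.  The substitution can therefore only be
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumstatsTable

__all__ = ["precision_filter", "fixed_effects_meta", "random_effects_update", "MetaResult"]

#: scale factor making the MAD a consistent SD estimator under normality
_MAD_TO_SD = 1.4826022185056018


@dataclass
class MetaResult:
    """Per-variant fixed- and random-effects meta-analysis statistics."""

    df: pd.DataFrame
    meta: dict

    def __len__(self) -> int:
        return len(self.df)


def precision_filter(
    a: SumstatsTable, b: SumstatsTable, k: float = 3.0
) -> tuple[np.ndarray, dict]:
    """Keep-mask over the harmonized pair by the robust precision-outlier rule.

    A variant is removed when its log(se_a/se_b) deviates from the median by
    more than ``k`` robust SDs (median absolute deviation scaled by 1.4826).
    If all ratios are identical (MAD = 0) nothing is removed.
    """
    if len(a) != len(b):
        raise ValueError("tables must be harmonized before precision_filter")
    log_ratio = np.log(a.df["se"].to_numpy(dtype=float)) - np.log(
        b.df["se"].to_numpy(dtype=float)
    )
    med = np.median(log_ratio)
    mad = np.median(np.abs(log_ratio - med))
    if mad == 0.0:
        keep = np.ones(len(a), dtype=bool)
    else:
        keep = np.abs(log_ratio - med) <= k * _MAD_TO_SD * mad
    counts = {"n_input": len(a), "n_removed_precision": int((~keep).sum()), "k": k}
    return keep, counts


def fixed_effects_meta(a: SumstatsTable, b: SumstatsTable) -> MetaResult:
    """Inverse-variance-weighted fixed-effects combination of the pair."""
    if len(a) != len(b):
        raise ValueError("tables must be harmonized before meta-analysis")
    beta_a = a.df["beta"].to_numpy(dtype=float)
    beta_b = b.df["beta"].to_numpy(dtype=float)
    se_a = a.df["se"].to_numpy(dtype=float)
    se_b = b.df["se"].to_numpy(dtype=float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise ValueError("non-positive standard error reached meta-analysis")

    w_a, w_b = 1.0 / se_a**2, 1.0 / se_b**2
    beta_fe = (beta_a * w_a + beta_b * w_b) / (w_a + w_b)
    se_fe = 1.0 / np.sqrt(w_a + w_b)
    z_fe = beta_fe / se_fe
    p_fe = 2.0 * stats.norm.sf(np.abs(z_fe))

    df = a.df[
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
    ].copy()
    df["beta_a"], df["se_a"] = beta_a, se_a
    df["beta_b"], df["se_b"] = beta_b, se_b
    df["beta_fe"], df["se_fe"], df["p_fe"] = beta_fe, se_fe, p_fe
    df["q_stat"] = np.nan
    df["tau2"] = np.nan
    df["beta_re"] = np.nan
    df["se_re"] = np.nan
    df["p_re"] = np.nan
    df["p_final"] = p_fe
    df["stage_flag"] = "fe_only"
    return MetaResult(df, {"studies": [a.trait_label, b.trait_label]})


def random_effects_update(
    fe: MetaResult, trigger_p: float = 1e-4, sig_threshold: float = 5e-8
) -> MetaResult:
    """DerSimonian-Laird random-effects substitution for triggered variants.

    For every variant with p_fe < ``trigger_p``: the two-study Q statistic
    gives tau2 = max(0, (Q - 1) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(se^2 + tau2) give beta_re/se_re/p_re, and
    p_final = max(p_fe, p_re) with stage_flag 're_substituted'.
    """
    df = fe.df.copy()
    trig = df["p_fe"].to_numpy() < trigger_p
    if trig.any():
        beta = df.loc[trig, ["beta_a", "beta_b"]].to_numpy(dtype=float)
        se = df.loc[trig, ["se_a", "se_b"]].to_numpy(dtype=float)
        w = 1.0 / se**2
        sw = w.sum(axis=1)
        beta_fe = (beta * w).sum(axis=1) / sw
        q = (w * (beta - beta_fe[:, None]) ** 2).sum(axis=1)
        # two studies -> Q has 1 degree of freedom
        c = sw - (w**2).sum(axis=1) / sw
        tau2 = np.maximum(0.0, (q - 1.0) / c)
        w_re = 1.0 / (se**2 + tau2[:, None])
        beta_re = (beta * w_re).sum(axis=1) / w_re.sum(axis=1)
        se_re = 1.0 / np.sqrt(w_re.sum(axis=1))
        p_re = 2.0 * stats.norm.sf(np.abs(beta_re / se_re))

        df.loc[trig, "q_stat"] = q
        df.loc[trig, "tau2"] = tau2
        df.loc[trig, "beta_re"] = beta_re
        df.loc[trig, "se_re"] = se_re
        df.loc[trig, "p_re"] = p_re
        df.loc[trig, "p_final"] = np.maximum(df.loc[trig, "p_fe"], p_re)
        df.loc[trig, "stage_flag"] = "re_substituted"
    meta = {
        **fe.meta,
        "trigger_p": trigger_p,
        "sig_threshold": sig_threshold,
        "n_triggered": int(trig.sum()),
        "n_significant_final": int((df["p_final"] < sig_threshold).sum()),
    }
    return MetaResult(df, meta)
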