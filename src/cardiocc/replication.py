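"""Replication statistics for novel loci.

Four checks against an independent dataset aligned to the discovery effect
alleles: exact binomial sign-concordance (null 50%), exact binomial nominal
replication at one-sided p < 0.05 (null 5%), discovery-vs-replication
effect-size correlation and regression, and allele-frequency enrichment of
case alleles against a reference panel by one-sided Fisher exact test.

One-sided replication p-values are oriented by the discovery sign:
p = 1 - Phi(z_repl * sign(beta_disc)).  Binomial tails are exact upper-tail
sums, P(X >= k | n, p0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicationInput",
    "sign_concordance_test",
    "nominal_replication_test",
    "af_enrichment_test",
    "effect_agreement",
    "binom_upper_tail",
]


@dataclass
class ReplicationInput:
    """Aligned discovery/replication effects for the testable variants.

    Columns: beta_disc, se_disc, beta_repl, se_repl (same effect allele after
    harmonization).  Variants untestable in replication are excluded upstream
    and reported separately, never imputed.
    """

    df: pd.DataFrame
    n_untestable: int = 0

    def __post_init__(self) -> None:
        required = {"beta_disc", "se_disc", "beta_repl", "se_repl"}
        if missing := required - set(self.df.columns):
            raise ValueError(f"ReplicationInput missing columns: {sorted(missing)}")

    @property
    def n_testable(self) -> int:
        return len(self.df)


def binom_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k | n, p0)."""
    return float(stats.binom.sf(k - 1, n, p0))


def sign_concordance_test(r: ReplicationInput) -> tuple[int, int, float]:
    """Count of concordant effect directions and its exact binomial p (null 0.5).

    Variants with a zero beta in either dataset carry no direction and are
    excluded from both k and n.
    """
    if r.n_testable < 1:
        raise ValueError("need at least one testable variant")
    b_d = r.df["beta_disc"].to_numpy(dtype=float)
    b_r = r.df["beta_repl"].to_numpy(dtype=float)
    usable = (b_d != 0) & (b_r != 0)
    if (~usable).any():
        logger.info("sign_concordance: excluded %d zero-beta variants", int((~usable).sum()))
    k = int((np.sign(b_d[usable]) == np.sign(b_r[usable])).sum())
    n = int(usable.sum())
    return k, n, binom_upper_tail(k, n, 0.5)


def one_sided_replication_p(r: ReplicationInput) -> np.ndarray:
    """Replication p oriented to the discovery direction: 1 - Phi(z * sign_disc)."""
    z = r.df["beta_repl"].to_numpy(dtype=float) / r.df["se_repl"].to_numpy(dtype=float)
    sign = np.sign(r.df["beta_disc"].to_numpy(dtype=float))
    return stats.norm.sf(z * sign)


def nominal_replication_test(
    r: ReplicationInput, alpha: float = 0.05, null_rate: float = 0.05
) -> tuple[int, int, float]:
    """Count of nominally replicating variants and its exact binomial p."""
    p_one = one_sided_replication_p(r)
    k = int((p_one < alpha).sum())
    n = r.n_testable
    return k, n, binom_upper_tail(k, n, null_rate)


def af_enrichment_test(
    case_counts: tuple[int, int],
    reference_counts: tuple[int, int],
    direction: int = 1,
) -> tuple[float, float, bool]:
    """Allele-count enrichment of cases vs a reference panel (additive coding).

    ``case_counts`` and ``reference_counts`` are (effect alleles, other
    alleles), two per individual.  Returns (odds ratio, one-sided Fisher p in
    the expected ``direction``, zero_margin_flag).  With a zero margin the
    odds ratio is undefined (NaN, flagged) but the p-value is still computed.
    """
    a, b = case_counts
    c, d = reference_counts
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    alternative = "greater" if direction >= 0 else "less"
    res = stats.fisher_exact(table, alternative=alternative)
    zero_margin = 0 in table.sum(axis=0) or 0 in table.sum(axis=1)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = a * d / (b * c)
    return odds, float(res.pvalue), bool(zero_margin)


def effect_agreement(r: ReplicationInput) -> dict:
    """Discovery-vs-replication effect correlation, p, and regression slope.

    The z-score variant is reported as a sensitivity output.
    """
    if r.n_testable < 3:
        raise ValueError("need at least three testable variants")
    b_d = r.df["beta_disc"].to_numpy(dtype=float)
    b_r = r.df["beta_repl"].to_numpy(dtype=float)
    if np.ptp(b_d) == 0 or np.ptp(b_r) == 0:
        raise ValueError("constant effect vector; correlation undefined")
    corr = stats.pearsonr(b_d, b_r)
    reg = stats.linregress(b_d, b_r)
    z_d = b_d / r.df["se_disc"].to_numpy(dtype=float)
    z_r = b_r / r.df["se_repl"].to_numpy(dtype=float)
    corr_z = stats.pearsonr(z_d, z_r)
    return {
        "r": float(corr.statistic),
        "p": float(corr.pvalue),
        "slope": float(reg.slope),
        "slope_se": float(reg.stderr),
        "r_z": float(corr_z.statistic),
        "p_z": float(corr_z.pvalue),
        "n": r.n_testable,
    }
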