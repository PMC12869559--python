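"""Polygenic-score construction, ancestry standardization and discrimination.

The score builder is a deliberately simple clump+threshold stand-in (greedy
distance-based clumping, best p first) so the evaluation machinery can be
exercised end to end on synthetic cohorts; it makes no claim to match
genome-wide Bayesian weighting methods.

Ancestry standardization follows the two-step recipe used for biobank PGS:
residualize the raw score on the leading principal components, model the log
of the squared residuals linearly on the PCs to obtain a per-individual
PC-predicted standard deviation (log-linear form guarantees positivity),
divide, and finally center/scale to mean 0, variance 1.

Discrimination metrics per contrast: odds ratio per SD of the adjusted score
(logistic model with covariates, Wald CI), AUC and AUPRC from the univariate
score (bootstrap CIs), Nagelkerke pseudo-R^2 gain over the covariate-only
model, and liability-scale R^2 gain via the standard prevalence-based
transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .simulate import Cohort
from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "build_simple_pgs",
    "standardize_pgs",
    "score_cohort",
    "evaluate_discrimination",
    "PgsEvalResult",
    "ScoredCohort",
]


@dataclass
class PgsEvalResult:
    contrast: str
    n_pos: int
    n_neg: int
    or_per_sd: float
    or_ci: tuple[float, float]
    p: float
    auc: float
    auc_ci: tuple[float, float]
    auprc: float
    auprc_ci: tuple[float, float]
    nagelkerke_r2_gain: float
    liability_r2_gain: float
    perfect_separation: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("or_per_sd", self.or_per_sd, *self.or_ci, self.p),
            ("auc", self.auc, *self.auc_ci, np.nan),
            ("auprc", self.auprc, *self.auprc_ci, np.nan),
            ("nagelkerke_r2_gain", self.nagelkerke_r2_gain, np.nan, np.nan, np.nan),
            ("liability_r2_gain", self.liability_r2_gain, np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(
            rows, columns=["metric", "estimate", "lo", "hi", "p"]
        ).assign(contrast=self.contrast)


@dataclass
class ScoredCohort:
    """Cohort with raw and ancestry-standardized scores attached."""

    cohort: Cohort
    raw_score: np.ndarray
    adjusted_score: np.ndarray
    orientation: str = "higher_score_higher_case_a_risk"
    meta: dict = field(default_factory=dict)


def build_simple_pgs(
    sumstats: SumstatsTable,
    p_threshold: float = 5e-8,
    merge_distance: int = 250_000,
) -> pd.DataFrame:
    """Greedy clump+threshold weights: best p first, suppress neighbours.

    Returns a DataFrame (variant_id, chrom, pos, effect_allele, beta) of the
    retained variants.  Warns (and returns empty) when nothing survives.
    """
    df = sumstats.df.sort_values("p", kind="stable")
    df = df.loc[df["p"] < p_threshold]
    kept_rows = []
    suppressed: dict[str, list[int]] = {}
    for _, row in df.iterrows():
        near = suppressed.get(row["chrom"], [])
        if any(abs(row["pos"] - q) <= merge_distance for q in near):
            continue
        kept_rows.append(row)
        suppressed.setdefault(row["chrom"], []).append(row["pos"])
    if not kept_rows:
        logger.warning(
            "build_simple_pgs(%s): no variants below p=%.3g",
            sumstats.trait_label,
            p_threshold,
        )
        return pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "effect_allele", "beta"]
        )
    out = pd.DataFrame(kept_rows)[
        ["variant_id", "chrom", "pos", "effect_allele", "beta"]
    ].reset_index(drop=True)
    return out


def standardize_pgs(raw: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """PC-residualized, PC-variance-normalized, z-scored score."""
    raw = np.asarray(raw, dtype=float)
    if raw.std() == 0:
        raise ValueError("constant score vector cannot be standardized")
    X = sm.add_constant(np.asarray(pcs, dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(f"rank-deficient PC matrix (columns {i} and {j} collinear)")
    resid = raw - X @ np.linalg.lstsq(X, raw, rcond=None)[0]
    # log-linear variance model: log(resid^2) ~ PCs -> predicted SD = exp(fit/2)
    log_sq = np.log(np.maximum(resid**2, 1e-300))
    pred = X @ np.linalg.lstsq(X, log_sq, rcond=None)[0]
    scaled = resid / np.exp(pred / 2.0)
    return (scaled - scaled.mean()) / scaled.std()


def score_cohort(
    cohort: Cohort, weights: pd.DataFrame, variant_ids: pd.Series
) -> ScoredCohort:
    """Apply PGS weights to cohort dosages and ancestry-standardize.

    ``variant_ids`` gives the id of each dosage column (the simulated panel's
    variant order).
    """
    idx = pd.Index(variant_ids)
    cols = idx.get_indexer(weights["variant_id"])
    if (cols < 0).any():
        missing = weights.loc[cols < 0, "variant_id"].tolist()[:5]
        raise KeyError(f"weight variants absent from cohort panel: {missing}...")
    raw = cohort.dosages[:, cols].astype(float) @ weights["beta"].to_numpy(dtype=float)
    adjusted = standardize_pgs(raw, cohort.pcs)
    return ScoredCohort(cohort, raw, adjusted)


def _nagelkerke(ll_full: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0


def _liability_r2(r2_obs: float, prevalence: float, sample_prev: float) -> float:
    """Lee-style observed-to-liability R^2 conversion.

    R2_liab = R2_obs * K^2 (1-K)^2 / (phi(tau)^2 P (1-P)).  At K = P = 0.5 the
    factor is pi/2, the familiar probit attenuation between the observed 0/1
    scale and the latent liability scale.
    """
    tau = stats.norm.isf(prevalence)
    phi = stats.norm.pdf(tau)
    k, p = prevalence, sample_prev
    factor = (k * (1 - k)) ** 2 / (phi**2 * p * (1 - p))
    return float(r2_obs * factor)


def evaluate_discrimination(
    scored: ScoredCohort,
    contrast: str,
    adjust: list[str] | None = None,
    prevalence: float | None = None,
    n_boot: int = 2_000,
    seed: int = 0,
    alpha_threshold: float = 0.05 / 9,
) -> PgsEvalResult:
    """Discrimination metrics for one contrast.

    ``contrast`` is one of ``a_vs_control``, ``b_vs_control``, ``a_vs_b``
    (positives listed first).  ``adjust`` names covariate columns (from the
    cohort covariates, plus ``pc<i>``); PCs are always included in the
    logistic model, age/sex only when requested (univariate AUC/AUPRC use the
    adjusted score alone).  ``prevalence`` feeds the liability-scale
    conversion (positive-class population prevalence); defaults to the sample
    prevalence of the contrast.
    """
    labels = scored.cohort.labels
    if contrast == "a_vs_control":
        mask = ~labels["case_b"]
        y = labels.loc[mask, "case_a"]
    elif contrast == "b_vs_control":
        mask = ~labels["case_a"]
        y = labels.loc[mask, "case_b"]
    elif contrast == "a_vs_b":
        mask = labels["case_a"] | labels["case_b"]
        y = labels.loc[mask, "case_a"]
    else:
        raise ValueError(f"unknown contrast '{contrast}'")
    y = y.to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"contrast '{contrast}' has an empty class")

    score = scored.adjusted_score[mask.to_numpy()]
    pcs = scored.cohort.pcs[mask.to_numpy()]
    covars = [pcs]
    for name in adjust or []:
        covars.append(scored.cohort.covariates.loc[mask, name].to_numpy()[:, None])
    X_cov = sm.add_constant(np.column_stack(covars))
    X_full = np.column_stack([X_cov, score])

    perfect = False
    try:
        fit_full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
        fit_cov = sm.Logit(y, X_cov).fit(disp=0, maxiter=200)
        coef = fit_full.params[-1]
        se = fit_full.bse[-1]
        if not np.isfinite(se) or se > 50:
            raise np.linalg.LinAlgError("separation")
        or_per_sd = float(np.exp(coef))
        ci = (float(np.exp(coef - 1.959964 * se)), float(np.exp(coef + 1.959964 * se)))
        p = float(fit_full.pvalues[-1])
        nk = _nagelkerke(fit_full.llf, fit_cov.llnull, len(y)) - _nagelkerke(
            fit_cov.llf, fit_cov.llnull, len(y)
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        perfect = True
        or_per_sd, ci, p, nk = float("inf"), (0.0, float("inf")), 0.0, 1.0
        logger.warning("perfect separation in contrast '%s'", contrast)

    auc = float(roc_auc_score(y, score))
    auprc = float(average_precision_score(y, score))
    rng = np.random.default_rng(seed)
    boots_auc, boots_pr = [], []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].sum() in (0, n):
            continue
        boots_auc.append(roc_auc_score(y[idx], score[idx]))
        boots_pr.append(average_precision_score(y[idx], score[idx]))
    if boots_auc:
        auc_ci = tuple(np.percentile(boots_auc, [2.5, 97.5]))
        pr_ci = tuple(np.percentile(boots_pr, [2.5, 97.5]))
    else:
        auc_ci = pr_ci = (np.nan, np.nan)

    # liability-scale R^2 gain from the observed-scale (OLS) R^2 gain
    sample_prev = float(y.mean())
    k = prevalence if prevalence is not None else sample_prev
    r2_full = np.corrcoef(sm.OLS(y, X_full).fit().fittedvalues, y)[0, 1] ** 2
    r2_cov = np.corrcoef(sm.OLS(y, X_cov).fit().fittedvalues, y)[0, 1] ** 2
    lia = _liability_r2(float(r2_full - r2_cov), k, sample_prev)

    return PgsEvalResult(
        contrast=contrast,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        or_per_sd=or_per_sd,
        or_ci=ci,
        p=p,
        auc=auc,
        auc_ci=auc_ci,
        auprc=auprc,
        auprc_ci=pr_ci,
        nagelkerke_r2_gain=float(nk),
        liability_r2_gain=lia,
        perfect_separation=perfect,
    )
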