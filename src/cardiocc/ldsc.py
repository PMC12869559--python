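"""Minimal LD-score-regression estimators.

Heritability is estimated by regressing per-variant chi-square statistics on
N * l_j / M (l_j the LD score, M the number of variants); the slope is the
heritability on the scale the z-scores are calibrated to (the standardized
case-control difference scale for binary traits analysed at n_eff/4, the
standardized-phenotype scale for quantitative traits), and the intercept
captures confounding/overlap.  Genetic covariance between two traits comes
from the analogous regression of z_a * z_b on sqrt(N_a N_b) * l_j / M, whose
intercept estimates the sampling covariance induced by sample overlap.

Standard errors and p-values are obtained by a delete-one block jackknife over
LD blocks (grouped into at most ``n_jackknife`` contiguous super-blocks).

A simplified method-of-moments regional-correlation scan, standing in for a
full local-genetic-correlation decomposition, implements the two-stage
Bonferroni scheme: regional heritability for both traits first, regional rg
only in regions passing stage 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LDReference
from .sumstats import SumstatsTable

__all__ = [
    "H2Estimate",
    "RgEstimate",
    "CrossTraitMoments",
    "cross_trait_moments",
    "estimate_h2",
    "estimate_rg",
    "regional_rg",
]

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


@dataclass
class H2Estimate:
    h2: float
    se: float
    intercept: float
    intercept_se: float
    lambda_gc: float
    n_variants: int

    @property
    def z(self) -> float:
        return self.h2 / self.se if self.se > 0 else np.inf

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


@dataclass
class RgEstimate:
    rg: float
    se: float
    p: float
    gencov: float
    gencov_se: float
    bivariate_intercept: float
    bivariate_intercept_se: float
    h2_a: H2Estimate
    h2_b: H2Estimate

    @property
    def out_of_range(self) -> bool:
        """Estimation noise is tolerated up to |rg| = 1.25; flagged beyond 1."""
        return abs(self.rg) > 1.0


def _super_blocks(ld: LDReference, n_jackknife: int) -> list[slice]:
    """Group contiguous LD blocks into ~n_jackknife jackknife units."""
    bounds = ld.block_bounds
    n_blocks = ld.n_blocks
    n_units = min(n_jackknife, n_blocks)
    edges = np.linspace(0, n_blocks, n_units + 1).round().astype(int)
    return [
        slice(int(bounds[edges[i]]), int(bounds[edges[i + 1]]))
        for i in range(n_units)
        if bounds[edges[i + 1]] > bounds[edges[i]]
    ]


def _wls_jackknife(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, units: list[slice]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted regression of y on [1, x]; delete-one-unit jackknife.

    Weights are held fixed across jackknife replicates.  Returns the full-data
    coefficients (intercept, slope), their jackknife SEs, and the per-replicate
    coefficient matrix (n_units, 2).
    """
    X = np.column_stack([np.ones_like(x), x])
    XtWX = (X * w[:, None]).T @ X
    XtWy = (X * w[:, None]).T @ y
    full = np.linalg.solve(XtWX, XtWy)

    reps = np.empty((len(units), 2))
    for i, sl in enumerate(units):
        Xs = X[sl]
        ws = w[sl]
        A = XtWX - (Xs * ws[:, None]).T @ Xs
        b = XtWy - (Xs * ws[:, None]).T @ y[sl]
        reps[i] = np.linalg.solve(A, b)
    g = len(units)
    se = np.sqrt((g - 1) / g * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    return full, se, reps


def _h2_weights(x: np.ndarray, l: np.ndarray, slope_guess: float) -> np.ndarray:
    """Heteroskedasticity + overcounting weights: 1 / (l_j * (1 + x_j h2)^2)."""
    return 1.0 / (np.maximum(l, 1.0) * (1.0 + np.maximum(slope_guess, 0.0) * x) ** 2)


def estimate_h2(
    table: SumstatsTable,
    ld: LDReference,
    weighted: bool = True,
    min_variants: int = 200,
    n_jackknife: int = 100,
) -> H2Estimate:
    """LD-score regression heritability with block-jackknife SE.

    The table must be aligned to ``ld``'s variant universe (same length and
    order).  Two-pass weighting: a first unweighted fit supplies the slope for
    the standard heteroskedasticity weights; ``weighted=False`` keeps the
    unweighted fit (the oracle-checkable mode).
    """
    if len(table) != ld.m:
        raise ValueError(
            f"table has {len(table)} variants but LD reference has {ld.m}; "
            "harmonize to the LD universe first"
        )
    if len(table) < min_variants:
        raise ValueError(
            f"refusing to estimate h2 from {len(table)} variants "
            f"(< {min_variants}); supply more data or lower min_variants"
        )
    z = table.df["z"].to_numpy(dtype=float)
    chi2 = z**2
    n = table.n_analysis.to_numpy(dtype=float)
    x = n * ld.ld_scores / ld.m
    units = _super_blocks(ld, n_jackknife)

    w = np.ones_like(x)
    if weighted:
        (_, slope0), _, _ = _wls_jackknife(x, chi2, w, units)
        w = _h2_weights(x, ld.ld_scores, slope0)
    (icpt, slope), (icpt_se, slope_se), _ = _wls_jackknife(x, chi2, w, units)
    lam = float(np.median(chi2) / _CHI2_MEDIAN_1DF)
    return H2Estimate(
        h2=float(slope),
        se=float(slope_se),
        intercept=float(icpt),
        intercept_se=float(icpt_se),
        lambda_gc=lam,
        n_variants=len(table),
    )


@dataclass
class CrossTraitMoments:
    """Raw bivariate regression quantities (no h2 normalization)."""

    gencov: float
    gencov_se: float
    intercept: float
    intercept_se: float


def cross_trait_moments(
    a: SumstatsTable,
    b: SumstatsTable,
    ld: LDReference,
    weighted: bool = True,
    n_jackknife: int = 100,
) -> CrossTraitMoments:
    """Slope (genetic covariance) and intercept (sampling covariance) of the
    z_a * z_b on sqrt(N_a N_b) l / M regression.

    Defined for null traits too (no division by heritability).
    """
    if len(a) != len(b) or len(a) != ld.m:
        raise ValueError("tables must be harmonized and aligned to the LD reference")
    z_a = a.df["z"].to_numpy(dtype=float)
    z_b = b.df["z"].to_numpy(dtype=float)
    x = np.sqrt(a.n_analysis.to_numpy(dtype=float) * b.n_analysis.to_numpy(dtype=float)) * ld.ld_scores / ld.m
    units = _super_blocks(ld, n_jackknife)
    y = z_a * z_b
    w = np.ones_like(x)
    if weighted:
        (_, guess), _, _ = _wls_jackknife(x, y, w, units)
        w = _h2_weights(x, ld.ld_scores, abs(guess))
    (icpt, gcov), (icpt_se, gcov_se), _ = _wls_jackknife(x, y, w, units)
    return CrossTraitMoments(float(gcov), float(gcov_se), float(icpt), float(icpt_se))


def estimate_rg(
    a: SumstatsTable,
    b: SumstatsTable,
    ld: LDReference,
    weighted: bool = True,
    n_jackknife: int = 100,
) -> RgEstimate:
    """Bivariate LD-score regression genetic correlation.

    rg = gencov / sqrt(h2_a * h2_b); the intercept of the cross-product
    regression estimates the sampling covariance from sample overlap.  The
    jackknife deletes each super-block from all three regressions jointly, so
    the rg SE propagates the uncertainty of both heritabilities.
    """
    if len(a) != len(b):
        raise ValueError("tables must be harmonized to the same variant universe")
    if len(a) != ld.m:
        raise ValueError("tables must be aligned to the LD reference")
    z_a = a.df["z"].to_numpy(dtype=float)
    z_b = b.df["z"].to_numpy(dtype=float)
    n_a = a.n_analysis.to_numpy(dtype=float)
    n_b = b.n_analysis.to_numpy(dtype=float)
    l = ld.ld_scores
    units = _super_blocks(ld, n_jackknife)

    x_a = n_a * l / ld.m
    x_b = n_b * l / ld.m
    x_ab = np.sqrt(n_a * n_b) * l / ld.m

    def fit(x, y):
        w = np.ones_like(x)
        if weighted:
            (_, slope_guess), _, _ = _wls_jackknife(x, y, w, units)
            w = _h2_weights(x, l, abs(slope_guess))
        return _wls_jackknife(x, y, w, units)

    (ia, ha), _, reps_a = fit(x_a, z_a**2)
    (ib, hb), _, reps_b = fit(x_b, z_b**2)
    (icpt, gcov), (icpt_se, gcov_se), reps_ab = fit(x_ab, z_a * z_b)

    if ha <= 0 or hb <= 0:
        raise ValueError(
            "rg undefined: non-positive heritability estimate "
            f"(h2_a={ha:.4g}, h2_b={hb:.4g})"
        )
    rg = gcov / np.sqrt(ha * hb)

    with np.errstate(invalid="ignore"):
        rg_reps = reps_ab[:, 1] / np.sqrt(
            np.maximum(reps_a[:, 1], 1e-12) * np.maximum(reps_b[:, 1], 1e-12)
        )
    g = len(rg_reps)
    rg_se = float(np.sqrt((g - 1) / g * ((rg_reps - rg_reps.mean()) ** 2).sum()))
    if rg_se > 0:
        p = float(2.0 * stats.norm.sf(abs(rg) / rg_se))
    else:
        p = 1.0 if rg == 0 else 0.0

    h2a_est = estimate_h2(a, ld, weighted=weighted, n_jackknife=n_jackknife)
    h2b_est = estimate_h2(b, ld, weighted=weighted, n_jackknife=n_jackknife)
    return RgEstimate(
        rg=float(rg),
        se=rg_se,
        p=p,
        gencov=float(gcov),
        gencov_se=float(gcov_se),
        bivariate_intercept=float(icpt),
        bivariate_intercept_se=float(icpt_se),
        h2_a=h2a_est,
        h2_b=h2b_est,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive (chrom, start, end) regions to BED half-open."""
    out = regions.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    return out


def bed_to_regions(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert BED 0-based half-open intervals to 1-based inclusive regions."""
    out = bed.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    return out


def _region_block_pairs(ld: LDReference, region: slice) -> float:
    """Number of correlated ordered pairs (j != k, same block) within region."""
    pairs = 0.0
    for sl in ld.block_slices():
        lo = max(sl.start, region.start)
        hi = min(sl.stop, region.stop)
        size = max(0, hi - lo)
        pairs += size * (size - 1)
    return pairs


def regional_rg(
    a: SumstatsTable,
    b: SumstatsTable,
    ld: LDReference,
    regions: list[slice] | None = None,
    alpha: float = 0.05,
    bivariate_intercept: float | None = None,
) -> pd.DataFrame:
    """Two-stage regional heritability / genetic-correlation scan.

    Stage 1 estimates per-region heritabilities by method of moments,
    h2_r = M_r * sum(chi2 - 1) / sum(N l), with a null variance computed from
    the known within-block correlation; regions where *both* traits pass
    two-sided P < alpha / n_regions are retained.  Stage 2 estimates regional
    rg in retained regions only, significant at P < alpha / n_retained.

    ``regions`` defaults to the LD blocks of the reference.  The global
    bivariate intercept (sampling covariance) is subtracted from the stage-2
    cross-products; if not supplied it is estimated genome-wide first.
    """
    if regions is None:
        regions = ld.block_slices()
    if bivariate_intercept is None:
        bivariate_intercept = estimate_rg(a, b, ld).bivariate_intercept

    z_a = a.df["z"].to_numpy(dtype=float)
    z_b = b.df["z"].to_numpy(dtype=float)
    n_a = a.n_analysis.to_numpy(dtype=float)
    n_b = b.n_analysis.to_numpy(dtype=float)
    l = ld.ld_scores
    rho = ld.rho

    rows = []
    for i, region in enumerate(regions):
        size = region.stop - region.start
        if size == 0:
            continue
        pairs = _region_block_pairs(ld, region)
        za, zb = z_a[region], z_b[region]
        la = l[region]
        na, nb = n_a[region], n_b[region]

        def mom_h2(z, n):
            num = float(np.sum(z**2 - 1.0))
            den = float(np.sum(n * la))
            h2_r = size * num / den if den > 0 else np.nan
            # null variance of sum(chi2): var 2 per variant, cov 2 rho^2 per
            # correlated pair (exact for the compound-symmetric blocks)
            var0 = 2.0 * size + 2.0 * rho**2 * pairs
            zstat = num / np.sqrt(var0)
            return h2_r, float(2.0 * stats.norm.sf(abs(zstat)))

        h2a_r, pa = mom_h2(za, na)
        h2b_r, pb = mom_h2(zb, nb)

        # stage-2 quantities (filled in below only for retained regions)
        mean_chi_a = float(np.mean(za**2))
        mean_chi_b = float(np.mean(zb**2))
        num = float(np.sum(za * zb - bivariate_intercept))
        den = float(np.sum(np.sqrt(na * nb) * la))
        gencov_r = size * num / den if den > 0 else np.nan
        var0 = mean_chi_a * mean_chi_b * (size + rho**2 * pairs)
        z_rg = num / np.sqrt(var0)
        p_rg = float(2.0 * stats.norm.sf(abs(z_rg)))
        rows.append(
            {
                "region": i,
                "start": region.start,
                "stop": region.stop,
                "n_variants": size,
                "h2_a": h2a_r,
                "p_h2_a": pa,
                "h2_b": h2b_r,
                "p_h2_b": pb,
                "gencov": gencov_r,
                "p_rg": p_rg,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    stage1_thresh = bonferroni_threshold(alpha, len(out))
    out["stage1_pass"] = (out["p_h2_a"] < stage1_thresh) & (
        out["p_h2_b"] < stage1_thresh
    )
    with np.errstate(invalid="ignore"):
        out["rg"] = out["gencov"] / np.sqrt(
            out["h2_a"].clip(lower=0) * out["h2_b"].clip(lower=0)
        )
    n_retained = int(out["stage1_pass"].sum())
    stage2_thresh = bonferroni_threshold(alpha, max(n_retained, 1))
    out["stage2_sig"] = out["stage1_pass"] & (out["p_rg"] < stage2_thresh)
    out.loc[~out["stage1_pass"], ["rg", "stage2_sig"]] = [np.nan, False]
    out.attrs["stage1_threshold"] = stage1_thresh
    out.attrs["stage2_threshold"] = stage2_thresh
    out.attrs["n_retained"] = n_retained
    return out
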