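"""Multi-trait (MTAG-style) update of a target scan from correlated traits.

All traits are harmonized to one variant universe and represented by
standardized marginal effects beta_hat_i = z_i / sqrt(N_i) with sampling
covariance Sigma / sqrt(N_i N_k) (Sigma the cross-trait sampling-correlation
matrix from bivariate LD-score intercepts, unit diagonal).  The per-variant
genetic covariance matrix Omega is estimated by method of moments from the
bivariate LD-score slopes (Omega_ik = gencov_ik / M), projected to the nearest
positive semi-definite matrix when needed.

The updated target effect at a variant is the generalized-least-squares
combination with weight vector w = Omega[:, t] / Omega[t, t]:

    beta_mtag = w' A^-1 beta_hat / (w' A^-1 w),   A = Omega - w Omega[:,t]' + Sigma_N

whose variance is 1 / (w' A^-1 w).  With a single trait, or with diagonal
Omega and Sigma, the update returns the input unchanged; with perfectly
proportional genetic effects it reduces to inverse-variance meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import RgEstimate, cross_trait_moments, estimate_h2, estimate_rg
from .simulate import LDReference
from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "MultiTraitModel",
    "select_secondary_traits",
    "estimate_omega_sigma",
    "mtag_combine",
]

MAX_TRAITS = 4  # desk-scale cap


@dataclass
class MultiTraitModel:
    """Genetic (omega) and sampling (sigma) covariance matrices across traits."""

    omega: np.ndarray
    sigma: np.ndarray
    trait_labels: list[str]
    psd_projection_distance: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = len(self.trait_labels)
        if self.omega.shape != (t, t) or self.sigma.shape != (t, t):
            raise ValueError("omega/sigma dimensions must match trait count")
        if not np.allclose(self.omega, self.omega.T) or not np.allclose(
            self.sigma, self.sigma.T
        ):
            raise ValueError("omega and sigma must be symmetric")
        eig = np.linalg.eigvalsh(self.sigma)
        if eig.min() <= 0:
            raise ValueError("sigma must be positive definite")


def select_secondary_traits(
    candidates: list[SumstatsTable],
    target: SumstatsTable,
    ld: LDReference,
    threshold: float = 0.65,
) -> list[tuple[SumstatsTable, RgEstimate]]:
    """Candidates whose |rg| with the target meets the threshold, by |rg| desc.

    Mirrors the secondary-trait selection rule for multi-trait boosting
    (substantial genetic correlation, typically |rg| > 0.65).
    """
    selected = []
    for cand in candidates:
        est = estimate_rg(cand, target, ld)
        if abs(est.rg) >= threshold:
            selected.append((cand, est))
        else:
            logger.info(
                "select_secondary_traits: '%s' excluded (|rg|=%.3f < %.2f)",
                cand.trait_label,
                abs(est.rg),
                threshold,
            )
    selected.sort(key=lambda t: abs(t[1].rg), reverse=True)
    return selected


def _project_psd(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue clipping at 0; returns (projected, Frobenius distance moved)."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= 0:
        return mat, 0.0
    clipped = np.clip(vals, 0.0, None)
    proj = (vecs * clipped) @ vecs.T
    proj = (proj + proj.T) / 2.0
    return proj, float(np.linalg.norm(proj - mat))


def estimate_omega_sigma(
    traits: list[SumstatsTable], ld: LDReference
) -> MultiTraitModel:
    """Method-of-moments omega and intercept-based sigma for a trait set."""
    t = len(traits)
    if t < 2:
        raise ValueError("need at least two traits")
    if t > MAX_TRAITS:
        raise ValueError(f"trait count capped at {MAX_TRAITS} for desk scale")
    for tr in traits[1:]:
        if len(tr) != len(traits[0]):
            raise ValueError("traits must be harmonized to a common universe")

    omega = np.zeros((t, t))
    sigma = np.eye(t)
    for i in range(t):
        omega[i, i] = estimate_h2(traits[i], ld).h2 / ld.m
    n_clipped = 0
    for i in range(t):
        for j in range(i + 1, t):
            mom = cross_trait_moments(traits[i], traits[j], ld)
            omega[i, j] = omega[j, i] = mom.gencov / ld.m
            # the intercept is a sampling *correlation*; it is weakly
            # identified when the polygenic signal is strong, so clip into the
            # admissible range for stability
            icpt = float(np.clip(mom.intercept, -0.95, 0.95))
            n_clipped += int(icpt != mom.intercept)
            sigma[i, j] = sigma[j, i] = icpt

    for _ in range(20):
        try:
            np.linalg.cholesky(sigma)
            break
        except np.linalg.LinAlgError:
            off = sigma - np.diag(np.diag(sigma))
            sigma = np.eye(t) + 0.9 * off
            n_clipped += 1
    else:
        pair = np.unravel_index(np.argmax(np.abs(sigma - np.eye(t))), sigma.shape)
        raise ValueError(
            "sampling covariance not invertible; offending trait pair: "
            f"({traits[pair[0]].trait_label}, {traits[pair[1]].trait_label})"
        )
    if n_clipped:
        logger.info("sigma intercepts clipped/shrunk %d times for stability", n_clipped)

    omega, dist = _project_psd(omega)
    if dist > 0:
        logger.info("omega projected to PSD cone; Frobenius distance %.3e", dist)
    return MultiTraitModel(
        omega=omega,
        sigma=sigma,
        trait_labels=[tr.trait_label for tr in traits],
        psd_projection_distance=dist,
    )


def mtag_combine(
    traits: list[SumstatsTable],
    model: MultiTraitModel,
    target_index: int = 0,
) -> SumstatsTable:
    """GLS multi-trait update of the target trait's statistics.

    Variants missing (NaN z) in any trait are excluded from the combination and
    counted in the output metadata.  The output carries updated z/p (and
    beta/se on the target's allele scale) plus an effective-sample-size gain
    summary computed from the mean-chi-square ratio (an approximation).
    """
    t = len(traits)
    if t != len(model.trait_labels):
        raise ValueError("model dimensions do not match trait count")
    target = traits[target_index]
    if t == 1:
        out = target.copy()
        out.meta["mtag_n_eff_gain"] = 0.0
        return out

    z = np.column_stack([tr.df["z"].to_numpy(dtype=float) for tr in traits])
    n = np.column_stack([tr.n_analysis.to_numpy(dtype=float) for tr in traits])
    complete = np.isfinite(z).all(axis=1) & np.isfinite(n).all(axis=1)
    n_excluded = int((~complete).sum())

    beta_std = z / np.sqrt(n)
    omega, sigma = model.omega, model.sigma
    w = omega[:, target_index] / omega[target_index, target_index]
    resid = omega - np.outer(w, omega[:, target_index])

    m = len(target)
    beta_out = np.full(m, np.nan)
    var_out = np.full(m, np.nan)

    # group variants by identical sampling-N rows: A is constant within a group
    idx_complete = np.flatnonzero(complete)
    n_round = n[idx_complete]
    _, group_ids = np.unique(n_round, axis=0, return_inverse=True)
    for gid in np.unique(group_ids):
        rows = idx_complete[group_ids == gid]
        n_vec = n[rows[0]]
        sigma_n = sigma / np.sqrt(np.outer(n_vec, n_vec))
        A = resid + sigma_n
        try:
            Ainv_w = np.linalg.solve(A, w)
        except np.linalg.LinAlgError:
            # fallback: pseudo-inverse for numerically singular A
            Ainv_w = np.linalg.pinv(A) @ w
        denom = float(w @ Ainv_w)
        beta_out[rows] = beta_std[rows] @ Ainv_w / denom
        var_out[rows] = 1.0 / denom

    z_out = beta_out / np.sqrt(var_out)
    p_out = 2.0 * stats.norm.sf(np.abs(z_out))

    df = target.df.copy()
    eaf = df["eaf"].to_numpy(dtype=float)
    gvar = 2.0 * eaf * (1.0 - eaf)
    df["z"] = z_out
    df["p"] = p_out
    df["beta"] = beta_out / np.sqrt(gvar)
    df["se"] = np.sqrt(var_out / gvar)
    df = df.loc[complete].reset_index(drop=True)

    chi_in = float(np.nanmean(z[complete, target_index] ** 2))
    chi_out = float(np.nanmean(z_out[complete] ** 2))
    gain = (chi_out - 1.0) / max(chi_in - 1.0, 1e-12) - 1.0
    meta = {
        **target.meta,
        "mtag_secondary_traits": [
            lbl for i, lbl in enumerate(model.trait_labels) if i != target_index
        ],
        "mtag_n_excluded": n_excluded,
        "mtag_mean_chi2_in": chi_in,
        "mtag_mean_chi2_out": chi_out,
        "mtag_n_eff_gain": gain,  # approximate N-scaling of the chi2 ratio
    }
    return SumstatsTable(f"{target.trait_label}_mtag", df, meta)
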