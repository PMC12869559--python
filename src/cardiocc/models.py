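"""Disease and cross-trait parameter models under the liability-threshold framework.

A binary disease is modelled as a latent standard-normal liability exceeding a
threshold tau = Phi^-1(1 - K), K the population prevalence.  Effect sizes live on
several interchangeable scales:

* liability scale  -- per-standardized-genotype effect beta_l on the latent liability;
* case-control (log-odds) scale -- the standardized-genotype mean difference between
  cases and controls, d = beta_l * phi(tau) / (K (1 - K)), which for small effects is
  also the per-standardized-genotype log-odds ratio;
* delta scale -- the standardized mean-genotype deviation of *cases from the
  population*, delta = beta_l * phi(tau) / K = d * (1 - K).  Case-case contrasts
  are naturally expressed on this scale.

Heritabilities transform quadratically: h2_d = h2_l * (phi(tau)/(K(1-K)))^2 and
h2_delta = h2_l * (phi(tau)/K)^2 = h2_d * (1-K)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DiseaseModel",
    "CrossTraitModel",
    "liability_threshold",
    "h2_liability_to_cc",
    "h2_cc_to_liability",
    "h2_liability_to_delta",
    "h2_observed_to_liability",
]


def liability_threshold(prevalence: float) -> float:
    """Liability threshold tau = Phi^-1(1 - K)."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")
    return float(stats.norm.isf(prevalence))


@dataclass(frozen=True)
class DiseaseModel:
    """Population and sampling parameters for one binary disorder."""

    label: str
    prevalence: float
    h2_liability: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"{self.label}: prevalence must be in (0,1)")
        if not 0.0 <= self.h2_liability < 1.0:
            raise ValueError(f"{self.label}: h2_liability must be in [0,1)")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError(f"{self.label}: case/control counts must be positive")

    @property
    def tau(self) -> float:
        return liability_threshold(self.prevalence)

    @property
    def phi_tau(self) -> float:
        """Normal density at the liability threshold."""
        return float(stats.norm.pdf(self.tau))

    @property
    def n_eff(self) -> float:
        """Effective sample size 4 / (1/n_case + 1/n_control)."""
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)

    @property
    def case_scale(self) -> float:
        """s = phi(tau)/K: liability-to-delta scale factor (cases vs population)."""
        return self.phi_tau / self.prevalence

    @property
    def cc_scale(self) -> float:
        """phi(tau)/(K(1-K)): liability-to-case-control (log-odds) scale factor."""
        return self.phi_tau / (self.prevalence * (1.0 - self.prevalence))

    @property
    def h2_delta(self) -> float:
        """Heritability on the case-vs-population delta scale."""
        return h2_liability_to_delta(self.h2_liability, self.prevalence)

    @property
    def h2_cc(self) -> float:
        """Heritability on the case-control (log-odds) scale."""
        return h2_liability_to_cc(self.h2_liability, self.prevalence)


def h2_liability_to_cc(h2_liability: float, prevalence: float) -> float:
    tau = liability_threshold(prevalence)
    phi = stats.norm.pdf(tau)
    return float(h2_liability * (phi / (prevalence * (1.0 - prevalence))) ** 2)


def h2_cc_to_liability(h2_cc: float, prevalence: float) -> float:
    tau = liability_threshold(prevalence)
    phi = stats.norm.pdf(tau)
    return float(h2_cc * (prevalence * (1.0 - prevalence) / phi) ** 2)


def h2_liability_to_delta(h2_liability: float, prevalence: float) -> float:
    tau = liability_threshold(prevalence)
    phi = stats.norm.pdf(tau)
    return float(h2_liability * (phi / prevalence) ** 2)


def h2_observed_to_liability(
    h2_obs: float, prevalence: float, sample_prevalence: float
) -> float:
    """Standard observed-scale (0/1 regression) to liability-scale conversion.

    h2_l = h2_obs * K^2 (1-K)^2 / (phi(tau)^2 * P (1-P)) with K the population
    prevalence and P the sample case fraction.
    """
    tau = liability_threshold(prevalence)
    phi = stats.norm.pdf(tau)
    k = prevalence
    p = sample_prevalence
    return float(h2_obs * (k * (1 - k)) ** 2 / (phi**2 * p * (1 - p)))


@dataclass
class CrossTraitModel:
    """Joint genetic architecture of a disease pair.

    ``error_covariance`` is the sampling correlation of the two studies' effect
    estimates (the bivariate LD-score intercept); ``m_causal`` the number of
    effectively independent causal variants; ``fst_causal`` the expected squared
    standardized case-group allele-frequency difference per causal variant, the
    genetic-distance parameter of the case-case reconstruction.
    """

    rg: float
    error_covariance: float = 0.0
    m_causal: int = 1
    fst_causal: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not -1.0 <= self.rg <= 1.0:
            raise ValueError(f"rg must be in [-1,1], got {self.rg}")
        if self.m_causal < 1:
            raise ValueError("m_causal must be >= 1")
        if self.fst_causal is not None and self.fst_causal < 0:
            raise ValueError("fst_causal must be >= 0")
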