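"""Synthetic GWAS summary statistics under a liability-threshold model.

The generator emulates the genetic architecture of a pair of rare, strongly
anticorrelated disorders (a DCM-like and an HCM-like cardiomyopathy): causal
liability effects drawn from a bivariate normal with per-trait variance
h2/m_causal and cross-trait correlation rg, converted to case-control summary
statistics through the liability-threshold model, with sampling covariance
across the pair induced by shared controls and block-compound-symmetric LD.

Because LD is compound symmetric within blocks, LD scores are known in closed
form (l_j = 1 + (block_size - 1) * rho^2) and are shipped with the data, making
LD-score regression testable without external reference panels.

Marginal z-scores for a binary trait are generated as

    z = sqrt(n_eff / 4) * (R d) + eps,    eps ~ N(0, R)

where d is the sparse vector of causal standardized case-control
mean-difference effects (d = beta_liability * phi(tau) / (K(1-K))), R the LD
matrix, and the eps of the two disorders correlate by
c = n_shared / sqrt(n_control_a * n_control_b) at each variant.  Per-allele
log-odds betas and standard errors are recovered via the small-effect
approximation beta = z * se, se = 1/sqrt((n_eff/4) * 2 p (1-p)).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import DiseaseModel
from .sumstats import SumstatsTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "LDReference",
    "Cohort",
    "default_config",
    "simulate_paired_sumstats",
    "simulate_replication_pair",
    "simulate_endophenotype",
    "simulate_cohort",
    "simulate_casecase_cohort",
]

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
    ("A", "T"), ("C", "G"),  # strand-ambiguous pairs, deliberately present
]


@dataclass(frozen=True)
class LDReference:
    """Block structure and per-variant LD scores of the synthetic genome.

    Blocks are compound symmetric with within-block correlation ``rho``; the
    LD score of every variant is therefore 1 + (block_size - 1) * rho^2.
    """

    block_bounds: np.ndarray  # (n_blocks+1,) variant-index boundaries
    ld_scores: np.ndarray  # (m,)
    rho: float

    @property
    def m(self) -> int:
        return int(self.block_bounds[-1])

    @property
    def n_blocks(self) -> int:
        return len(self.block_bounds) - 1

    def block_slices(self) -> list[slice]:
        return [
            slice(int(self.block_bounds[i]), int(self.block_bounds[i + 1]))
            for i in range(self.n_blocks)
        ]

    @classmethod
    def from_block_sizes(cls, sizes: Sequence[int], rho: float) -> "LDReference":
        if not 0.0 <= rho < 1.0:
            raise ValueError("within-block correlation must be in [0,1)")
        sizes = np.asarray(sizes, dtype=int)
        if (sizes < 1).any():
            raise ValueError("block sizes must be >= 1")
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        l = np.repeat(1.0 + (sizes - 1) * rho**2, sizes)
        return cls(block_bounds=bounds, ld_scores=l, rho=rho)

    @classmethod
    def compound_symmetric(cls, m: int, block_size: int, rho: float) -> "LDReference":
        """Uniform blocks of ``block_size`` (last block truncated)."""
        full, rem = divmod(m, block_size)
        sizes = [block_size] * full + ([rem] if rem else [])
        return cls.from_block_sizes(sizes, rho)

    @classmethod
    def mixed_blocks(cls, m: int, mean_block_size: int, rho: float) -> "LDReference":
        """Deterministic spread of block sizes around the mean.

        LD-score regression needs variation in l_j to separate slope from
        intercept, so the synthetic genome cycles block sizes through
        {0.2, 0.6, 1.0, 1.4, 1.8} x mean, interleaved with runs of singleton
        (LD-free, l_j = 1) blocks that anchor the intercept.
        """
        pattern = [
            max(1, round(f * mean_block_size)) for f in (0.2, 0.6, 1.0, 1.4, 1.8)
        ]
        # one singleton run (~20% of the mean size) after each proper block
        singletons = [1] * max(1, round(0.2 * mean_block_size))
        pattern = [s for b in pattern for s in ([b] + singletons)]
        sizes: list[int] = []
        total = 0
        i = 0
        while total < m:
            s = min(pattern[i % len(pattern)], m - total)
            sizes.append(s)
            total += s
            i += 1
        return cls.from_block_sizes(sizes, rho)


@dataclass
class SimulationConfig:
    """Study conditions for the paired-disorder simulation.

    Defaults mirror the cardiomyopathy study: DCM-like prevalence 0.4% with
    liability h2 14.2% (9,365 cases / 1,199,156 controls), HCM-like prevalence
    0.2% with liability h2 18% (5,900 cases / 68,359 controls), cross-disorder
    rg -0.58, and a shared-control count chosen so the induced sampling
    correlation of effect estimates is ~0.012.  The variant panel is scaled to
    desk size (50k variants, 1,200 causal) with the causal count matching the
    study's ~1,223 effectively independent causal variants.
    """

    m_variants: int = 50_000
    m_causal: int = 1_200
    ld_block_size: int = 50
    within_block_corr: float = 0.5
    disease_a: DiseaseModel = field(
        default_factory=lambda: DiseaseModel("DCM_like", 0.004, 0.142, 9_365, 1_199_156)
    )
    disease_b: DiseaseModel = field(
        default_factory=lambda: DiseaseModel("HCM_like", 0.002, 0.180, 5_900, 68_359)
    )
    rg: float = -0.58
    shared_controls: int = 3_400
    endophenotypes: Sequence[tuple[str, float, float]] = field(
        default_factory=lambda: [
            # (label, h2, rg with the case-case causal axis) -- the three
            # MRI endophenotype correlations reported for the case-case scan.
            ("strain_like", 0.30, 0.793),
            ("volume_like", 0.30, 0.711),
            ("concentricity_like", 0.30, -0.668),
        ]
    )
    endophenotype_n: int = 36_083
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_causal > self.m_variants:
            raise ValueError("m_causal must be <= m_variants")
        if not -1.0 <= self.rg <= 1.0:
            raise ValueError("rg must be in [-1,1]")
        if self.shared_controls < 0:
            raise ValueError("shared_controls must be >= 0")
        self.shared_controls = min(
            self.shared_controls, self.disease_a.n_control, self.disease_b.n_control
        )

    @property
    def overlap_corr(self) -> float:
        """Induced per-variant sampling correlation of the two z-scores."""
        return self.shared_controls / np.sqrt(
            self.disease_a.n_control * self.disease_b.n_control
        )


def default_config(**overrides) -> SimulationConfig:
    """The study-condition configuration, with keyword overrides."""
    return SimulationConfig(**overrides)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated data for recovery tests."""

    causal_index: np.ndarray
    beta_liability_a: np.ndarray  # (m_causal,)
    beta_liability_b: np.ndarray
    eaf: np.ndarray  # (m,)
    realized_rg: float
    ld: LDReference
    overlap_corr: float
    seed: int
    config: SimulationConfig

    @property
    def delta_a(self) -> np.ndarray:
        """Causal effects on the case-vs-population delta scale, disorder A."""
        return self.beta_liability_a * self.config.disease_a.case_scale

    @property
    def delta_b(self) -> np.ndarray:
        return self.beta_liability_b * self.config.disease_b.case_scale

    @property
    def casecase_axis(self) -> np.ndarray:
        """Causal case-case (A-cases minus B-cases) delta-scale effects."""
        return self.delta_a - self.delta_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "causal_index": self.causal_index,
                "beta_liability_a": self.beta_liability_a,
                "beta_liability_b": self.beta_liability_b,
                "delta_a": self.delta_a,
                "delta_b": self.delta_b,
            }
        )


def _positions(m: int, ld: LDReference) -> tuple[np.ndarray, np.ndarray]:
    """Assign blocks round-robin to chromosomes 1..22, 10 kb variant spacing."""
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    offsets = dict.fromkeys(range(1, 23), 1_000_000)
    for i, sl in enumerate(ld.block_slices()):
        c = (i % 22) + 1
        size = sl.stop - sl.start
        start = offsets[c]
        chrom[sl] = str(c)
        pos[sl] = start + 10_000 * np.arange(size)
        # 2 Mb gap between blocks on the same chromosome so that distinct
        # blocks never merge into one locus by the 1 Mb rule.
        offsets[c] = start + 10_000 * size + 2_000_000
    return chrom, pos


def _draw_block_noise(
    rng: np.random.Generator, ld: LDReference, n_traits: int, cross_corr: np.ndarray
) -> np.ndarray:
    """Draw (n_traits, m) noise with within-block CS correlation rho per trait
    and cross-trait correlation ``cross_corr`` at matched variants."""
    m = ld.m
    rho = ld.rho
    chol = np.linalg.cholesky(cross_corr)
    # variant-specific part
    e = chol @ rng.standard_normal((n_traits, m))
    # block-shared part
    u = chol @ rng.standard_normal((n_traits, ld.n_blocks))
    out = np.sqrt(1.0 - rho) * e
    for i, sl in enumerate(ld.block_slices()):
        out[:, sl] += np.sqrt(rho) * u[:, [i]]
    return out


def _smear(vec: np.ndarray, ld: LDReference) -> np.ndarray:
    """R @ vec for blockwise compound-symmetric R."""
    out = (1.0 - ld.rho) * vec
    for sl in ld.block_slices():
        out[sl] += ld.rho * vec[sl].sum()
    return out


def _draw_causal_effects(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal causal liability effects with correlation rg."""
    mc = cfg.m_causal
    sa = np.sqrt(cfg.disease_a.h2_liability / mc)
    sb = np.sqrt(cfg.disease_b.h2_liability / mc)
    x = rng.standard_normal(mc)
    y = cfg.rg * x + np.sqrt(max(0.0, 1.0 - cfg.rg**2)) * rng.standard_normal(mc)
    return sa * x, sb * y


def _table_from_z(
    label: str,
    z: np.ndarray,
    eaf: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    alleles: tuple[np.ndarray, np.ndarray],
    n_analysis: float,
    n_case: int | None,
    n_control: int | None,
    n_total: int | None,
) -> SumstatsTable:
    se = 1.0 / np.sqrt(n_analysis * 2.0 * eaf * (1.0 - eaf))
    beta = z * se
    df = pd.DataFrame(
        {
            "variant_id": [
                f"{c}:{p}:{o}:{e}"
                for c, p, o, e in zip(chrom, pos, alleles[1], alleles[0])
            ],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": alleles[0],
            "other_allele": alleles[1],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "z": z,
            "n_case": n_case,
            "n_control": n_control,
            "n": n_total,
        }
    )
    return SumstatsTable(label, df)


def simulate_paired_sumstats(
    cfg: SimulationConfig | None = None,
) -> tuple[SumstatsTable, SumstatsTable, SyntheticTruth]:
    """Generate the paired case-control summary statistics and ground truth."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_variants
    ld = LDReference.mixed_blocks(m, cfg.ld_block_size, cfg.within_block_corr)

    chrom, pos = _positions(m, ld)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    eff = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oth = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    eaf = rng.uniform(0.05, 0.95, size=m)

    # the small-effect liability->log-odds conversion breaks down for huge
    # per-variant effects; refuse clearly divergent parameterizations
    per_causal_sd = max(
        np.sqrt(cfg.disease_a.h2_liability / cfg.m_causal),
        np.sqrt(cfg.disease_b.h2_liability / cfg.m_causal),
    )
    if per_causal_sd > 0.5:
        raise ValueError(
            "divergent causal liability effects: h2 too large for m_causal "
            f"(per-causal effect SD {per_causal_sd:.2f} > 0.5)"
        )

    causal = np.sort(rng.choice(m, size=cfg.m_causal, replace=False))
    bl_a, bl_b = _draw_causal_effects(rng, cfg)

    da_model, db_model = cfg.disease_a, cfg.disease_b
    d_a = np.zeros(m)
    d_b = np.zeros(m)
    d_a[causal] = bl_a * da_model.cc_scale
    d_b[causal] = bl_b * db_model.cc_scale

    c = cfg.overlap_corr
    noise = _draw_block_noise(rng, ld, 2, np.array([[1.0, c], [c, 1.0]]))
    z_a = np.sqrt(da_model.n_eff / 4.0) * _smear(d_a, ld) + noise[0]
    z_b = np.sqrt(db_model.n_eff / 4.0) * _smear(d_b, ld) + noise[1]

    table_a = _table_from_z(
        da_model.label, z_a, eaf, chrom, pos, (eff, oth),
        da_model.n_eff / 4.0, da_model.n_case, da_model.n_control,
        da_model.n_case + da_model.n_control,
    )
    table_b = _table_from_z(
        db_model.label, z_b, eaf, chrom, pos, (eff, oth),
        db_model.n_eff / 4.0, db_model.n_case, db_model.n_control,
        db_model.n_case + db_model.n_control,
    )

    if cfg.m_causal >= 2 and np.std(bl_a) > 0 and np.std(bl_b) > 0:
        realized_rg = float(np.corrcoef(bl_a, bl_b)[0, 1])
    else:
        realized_rg = float("nan")
    truth = SyntheticTruth(
        causal_index=causal,
        beta_liability_a=bl_a,
        beta_liability_b=bl_b,
        eaf=eaf,
        realized_rg=realized_rg,
        ld=ld,
        overlap_corr=c,
        seed=cfg.seed,
        config=cfg,
    )
    return table_a, table_b, truth


def simulate_replication_pair(
    truth: SyntheticTruth,
    seed: int,
    disease_a: DiseaseModel | None = None,
    disease_b: DiseaseModel | None = None,
) -> tuple[SumstatsTable, SumstatsTable]:
    """Fresh summary statistics for the *same* causal architecture.

    An independent cohort measuring the same disorders: identical truth
    effects and LD, new sampling noise, optionally different case/control
    counts (replication cohorts are typically smaller).
    """
    cfg = truth.config
    da = disease_a or cfg.disease_a
    db = disease_b or cfg.disease_b
    rng = np.random.default_rng(seed)
    ld = truth.ld
    m = ld.m
    d_a = np.zeros(m)
    d_b = np.zeros(m)
    d_a[truth.causal_index] = truth.beta_liability_a * da.cc_scale
    d_b[truth.causal_index] = truth.beta_liability_b * db.cc_scale
    noise = _draw_block_noise(rng, ld, 2, np.eye(2))
    z_a = np.sqrt(da.n_eff / 4.0) * _smear(d_a, ld) + noise[0]
    z_b = np.sqrt(db.n_eff / 4.0) * _smear(d_b, ld) + noise[1]
    chrom, pos = _positions(m, ld)
    eff = np.array(["A"] * m, dtype=object)
    oth = np.array(["G"] * m, dtype=object)
    table_a = _table_from_z(
        f"{da.label}_repl", z_a, truth.eaf, chrom, pos, (eff, oth),
        da.n_eff / 4.0, da.n_case, da.n_control, da.n_case + da.n_control,
    )
    table_b = _table_from_z(
        f"{db.label}_repl", z_b, truth.eaf, chrom, pos, (eff, oth),
        db.n_eff / 4.0, db.n_case, db.n_control, db.n_case + db.n_control,
    )
    return table_a, table_b


def simulate_endophenotype(
    truth: SyntheticTruth,
    label: str,
    h2: float,
    rg_with_axis: float,
    n: int | None = None,
    seed: int | None = None,
) -> SumstatsTable:
    """Quantitative-trait summary statistics correlated with the case-case axis.

    Causal effects are drawn with correlation ``rg_with_axis`` to the causal
    case-case (delta-scale) axis of ``truth`` and per-variant variance
    h2/m_causal; z-scores follow the same LD and noise model as the disease
    scans (no sample overlap with them).
    """
    cfg = truth.config
    n = n if n is not None else cfg.endophenotype_n
    rng = np.random.default_rng(
        seed if seed is not None else truth.seed + zlib.crc32(label.encode()) % 100_000
    )
    axis = truth.casecase_axis
    sd_axis = axis.std()
    if sd_axis == 0:
        raise ValueError("degenerate case-case axis (no causal variance)")
    unit = (axis - axis.mean()) / sd_axis
    scale = np.sqrt(h2 / cfg.m_causal)
    r = rg_with_axis
    beta = scale * (r * unit + np.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(len(unit)))

    ld = truth.ld
    b_full = np.zeros(ld.m)
    b_full[truth.causal_index] = beta
    noise = _draw_block_noise(rng, ld, 1, np.array([[1.0]]))[0]
    z = np.sqrt(n) * _smear(b_full, ld) + noise

    chrom, pos = _positions(ld.m, ld)
    # reuse the disease panel's variant identities so harmonization is trivial
    eff = np.array(["A"] * ld.m, dtype=object)
    oth = np.array(["G"] * ld.m, dtype=object)
    table = _table_from_z(
        label, z, truth.eaf, chrom, pos, (eff, oth), float(n), None, None, n
    )
    table.meta["rg_with_axis"] = rg_with_axis
    table.meta["orientation"] = "positive_loads_casecase_axis"
    return table


@dataclass
class Cohort:
    """Small individual-level cohort with dosages, labels and covariates."""

    dosages: np.ndarray  # (n, m)
    labels: pd.DataFrame  # boolean columns case_a, case_b
    pcs: np.ndarray  # (n, n_pcs)
    covariates: pd.DataFrame  # age, sex
    eaf: np.ndarray
    liability_a: np.ndarray
    liability_b: np.ndarray


def _genotypes(
    rng: np.random.Generator,
    eaf: np.ndarray,
    n: int,
    n_pcs: int,
    ancestry_strength: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant binomial dosages with an optional ancestry gradient loaded
    on latent factors returned as PC covariates."""
    m = len(eaf)
    factors = rng.standard_normal((n, n_pcs))
    if ancestry_strength > 0:
        loadings = rng.standard_normal((n_pcs, m)) * ancestry_strength
        p = np.clip(eaf[None, :] + factors @ loadings, 0.01, 0.99)
    else:
        p = np.broadcast_to(eaf, (n, m))
    dosages = rng.binomial(2, p).astype(np.float32)
    return dosages, factors


def _liabilities(
    rng: np.random.Generator, dosages: np.ndarray, truth: SyntheticTruth
) -> tuple[np.ndarray, np.ndarray]:
    cfg = truth.config
    g = dosages[:, truth.causal_index].astype(float)
    p = truth.eaf[truth.causal_index]
    g = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    n = len(dosages)
    lia_a = g @ truth.beta_liability_a + rng.standard_normal(n) * np.sqrt(
        max(0.0, 1.0 - cfg.disease_a.h2_liability)
    )
    lia_b = g @ truth.beta_liability_b + rng.standard_normal(n) * np.sqrt(
        max(0.0, 1.0 - cfg.disease_b.h2_liability)
    )
    return lia_a, lia_b


def simulate_cohort(
    truth: SyntheticTruth,
    n_individuals: int,
    n_pcs: int = 4,
    ancestry_strength: float = 0.0,
    seed: int | None = None,
) -> Cohort:
    """Unascertained individual-level cohort drawn from the truth effects.

    Genotypes are binomial at the configured frequencies (with an optional
    ancestry gradient loaded on the leading PCs); liabilities combine the truth
    causal effects with residual normal noise; labels threshold each liability
    at its disease-specific prevalence.
    """
    cfg = truth.config
    if n_individuals > 50_000 or truth.ld.m > 5_000:
        raise ValueError("cohort request exceeds desk scale (<=50k x <=5k variants)")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else truth.seed + 1)
    dosages, factors = _genotypes(rng, truth.eaf, n_individuals, n_pcs, ancestry_strength)
    lia_a, lia_b = _liabilities(rng, dosages, truth)
    labels = pd.DataFrame(
        {
            "case_a": lia_a > cfg.disease_a.tau,
            "case_b": lia_b > cfg.disease_b.tau,
        }
    )
    covars = pd.DataFrame(
        {
            "age": rng.normal(55, 10, n_individuals),
            "sex": rng.integers(0, 2, n_individuals),
        }
    )
    return Cohort(dosages, labels, factors, covars, truth.eaf, lia_a, lia_b)


def simulate_casecase_cohort(
    truth: SyntheticTruth,
    n_case_a: int,
    n_case_b: int,
    n_controls: int = 0,
    n_pcs: int = 4,
    seed: int | None = None,
    batch: int = 20_000,
    max_batches: int = 2_000,
) -> Cohort:
    """Ascertained cohort with fixed case counts for both disorders.

    Individuals are drawn in batches; liabilities are computed from causal
    genotypes only, cases (and the requested controls) retained, and
    non-causal genotypes filled in afterwards for the retained individuals.
    """
    cfg = truth.config
    if truth.ld.m > 5_000:
        raise ValueError("cohort request exceeds desk scale (<=5k variants)")
    rng = np.random.default_rng(seed if seed is not None else truth.seed + 2)
    p_causal = truth.eaf[truth.causal_index]
    tau_a, tau_b = cfg.disease_a.tau, cfg.disease_b.tau

    kept_g: list[np.ndarray] = []
    kept_la: list[np.ndarray] = []
    kept_lb: list[np.ndarray] = []
    counts = {"a": 0, "b": 0, "ctl": 0}
    for _ in range(max_batches):
        g = rng.binomial(2, p_causal, size=(batch, len(p_causal))).astype(np.float32)
        gs = (g - 2 * p_causal) / np.sqrt(2 * p_causal * (1 - p_causal))
        la = gs @ truth.beta_liability_a + rng.standard_normal(batch) * np.sqrt(
            max(0.0, 1.0 - cfg.disease_a.h2_liability)
        )
        lb = gs @ truth.beta_liability_b + rng.standard_normal(batch) * np.sqrt(
            max(0.0, 1.0 - cfg.disease_b.h2_liability)
        )
        is_a = la > tau_a
        is_b = lb > tau_b
        want = np.zeros(batch, dtype=bool)
        want |= is_a & (counts["a"] < n_case_a)
        want |= is_b & (counts["b"] < n_case_b)
        if counts["ctl"] < n_controls:
            ctl = ~is_a & ~is_b
            idx = np.flatnonzero(ctl)[: n_controls - counts["ctl"]]
            take_ctl = np.zeros(batch, dtype=bool)
            take_ctl[idx] = True
            want |= take_ctl
            counts["ctl"] += int(take_ctl.sum())
        counts["a"] += int((is_a & want).sum())
        counts["b"] += int((is_b & want).sum())
        kept_g.append(g[want])
        kept_la.append(la[want])
        kept_lb.append(lb[want])
        if counts["a"] >= n_case_a and counts["b"] >= n_case_b and counts["ctl"] >= n_controls:
            break
    else:
        raise RuntimeError("failed to collect requested case counts")

    g_causal = np.concatenate(kept_g)
    la = np.concatenate(kept_la)
    lb = np.concatenate(kept_lb)
    n = len(g_causal)
    dosages = rng.binomial(2, truth.eaf, size=(n, truth.ld.m)).astype(np.float32)
    dosages[:, truth.causal_index] = g_causal
    labels = pd.DataFrame({"case_a": la > tau_a, "case_b": lb > tau_b})
    factors = rng.standard_normal((n, n_pcs))
    covars = pd.DataFrame(
        {"age": rng.normal(55, 10, n), "sex": rng.integers(0, 2, n)}
    )
    return Cohort(dosages, labels, factors, covars, truth.eaf, la, lb)
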