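"""Reading, validation, harmonization and QC of GWAS summary-statistics tables.

Every downstream stage of the pipeline consumes the canonical representation
defined here: a :class:`SumstatsTable` wrapping a pandas DataFrame with one row
per variant and a fixed column vocabulary.  Coordinates are 1-based inclusive
throughout; the genome build is carried as metadata and never inferred.

Variants are keyed by (chrom, pos, unordered allele pair); rsIDs/variant ids are
carried along but never used as the join key, for robustness to identifier drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SumstatsTable",
    "QCConfig",
    "MYBPC3_REGION",
    "read_sumstats",
    "write_sumstats",
    "harmonize_pair",
    "apply_qc",
    "z_from_p",
]

#: Canonical per-variant columns.  n_case/n_control/n are optional.
CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "z",
    "n_case",
    "n_control",
    "n",
]

#: Extended MYBPC3 region excluded in the cardiomyopathy analyses (1-based, GRCh38).
MYBPC3_REGION = ("11", 29_978_453, 80_288_956)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Relative tolerance beyond which a stored z disagreeing with beta/se is replaced.
Z_CONSISTENCY_RTOL = 1e-3


def z_from_p(p: np.ndarray | float, sign: np.ndarray | float) -> np.ndarray:
    """Two-sided p to signed z: z = sign * Phi^-1(1 - p/2)."""
    return np.sign(sign) * stats.norm.isf(np.asarray(p, dtype=float) / 2.0)


@dataclass
class SumstatsTable:
    """Canonical per-variant association records for one trait.

    ``df`` holds the canonical columns; ``meta`` free-form provenance
    (genome build, filter counts, conversion constants).
    """

    trait_label: str
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def is_binary(self) -> bool:
        return "n_case" in self.df and self.df["n_case"].notna().any()

    @property
    def n_eff(self) -> pd.Series:
        """Effective sample size 4/(1/n_case + 1/n_control) for binary traits."""
        if not self.is_binary:
            raise ValueError(f"{self.trait_label}: not a binary trait")
        return 4.0 / (1.0 / self.df["n_case"] + 1.0 / self.df["n_control"])

    @property
    def n_analysis(self) -> pd.Series:
        """Per-variant sample size on the scale the z-scores are calibrated to.

        For binary traits this is n_eff/4 (the variance of the standardized
        case-control mean-difference estimate is its reciprocal); for
        quantitative traits it is n.
        """
        if self.is_binary:
            return self.n_eff / 4.0
        return self.df["n"].astype(float)

    def key_frame(self) -> pd.DataFrame:
        """(chrom, pos, unordered allele pair) join keys."""
        a1 = self.df["effect_allele"].str.upper()
        a2 = self.df["other_allele"].str.upper()
        lo = np.minimum(a1, a2)
        hi = np.maximum(a1, a2)
        return pd.DataFrame(
            {
                "chrom": self.df["chrom"].astype(str),
                "pos": self.df["pos"].astype(int),
                "allele_lo": lo,
                "allele_hi": hi,
            },
            index=self.df.index,
        )

    def copy(self) -> "SumstatsTable":
        return SumstatsTable(self.trait_label, self.df.copy(), dict(self.meta))


@dataclass
class QCConfig:
    """Variant-level filtering configuration.

    ``min_fraction_n`` retains variants whose (effective or total, per
    ``n_mode``) sample size is at least that fraction of the table maximum;
    ``excluded_regions`` are 1-based inclusive (chrom, start, end) intervals.
    """

    min_fraction_n: float | None = None
    n_mode: str = "effective"
    excluded_regions: Sequence[tuple[str, int, int]] = field(default_factory=list)
    min_eaf: float = 0.0
    remove_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.min_fraction_n is not None and not 0.0 < self.min_fraction_n <= 1.0:
            raise ValueError(
                f"min_fraction_n must be in (0,1], got {self.min_fraction_n}"
            )
        if self.n_mode not in ("effective", "total"):
            raise ValueError(f"n_mode must be 'effective' or 'total', got {self.n_mode}")
        for chrom, start, end in self.excluded_regions:
            if start > end:
                raise ValueError(f"excluded region {chrom}:{start}-{end} has start > end")


def _is_ambiguous(effect: pd.Series, other: pd.Series) -> pd.Series:
    """Strand-ambiguous (A/T or C/G) variant mask."""
    comp = effect.str.upper().map(_COMPLEMENT)
    return comp == other.str.upper()


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    sep: str = "\t",
) -> SumstatsTable:
    """Read a tab-delimited summary-statistics file into the canonical form.

    ``dialect`` maps canonical column names to the file's column names; columns
    already canonically named need no entry.  Gzip is handled transparently.
    Missing z is reconstructed from beta/se, or from p and the sign of beta;
    missing p from z.  Rows violating basic invariants (se <= 0, eaf outside
    (0,1), p outside (0,1], non-numeric effect fields) are dropped and counted
    in ``meta['rows_dropped']``.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    dialect = dict(dialect or {})
    rename = {v: k for k, v in dialect.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    mandatory = ["chrom", "pos", "effect_allele", "other_allele", "eaf"]
    for col in mandatory:
        if col not in raw.columns:
            raise KeyError(f"missing mandatory column '{col}' (check the dialect mapping)")
    if "beta" not in raw.columns and "z" not in raw.columns:
        raise KeyError("missing mandatory effect column: need 'beta' or 'z'")
    if "se" not in raw.columns and "p" not in raw.columns:
        raise KeyError("missing mandatory column: need 'se' or 'p'")

    df = pd.DataFrame()
    df["chrom"] = raw["chrom"].astype(str).str.replace("^chr", "", regex=True)
    df["pos"] = pd.to_numeric(raw["pos"], errors="coerce")
    df["effect_allele"] = raw["effect_allele"].str.upper()
    df["other_allele"] = raw["other_allele"].str.upper()
    for col in ["eaf", "beta", "se", "p", "z", "n_case", "n_control", "n"]:
        if col in raw.columns:
            df[col] = pd.to_numeric(raw[col], errors="coerce")
        else:
            df[col] = np.nan
    if "variant_id" in raw.columns:
        df.insert(0, "variant_id", raw["variant_id"].astype(str))
    else:
        df.insert(
            0,
            "variant_id",
            df["chrom"].astype(str)
            + ":"
            + df["pos"].astype("Int64").astype(str)
            + ":"
            + df["other_allele"]
            + ":"
            + df["effect_allele"],
        )

    n_in = len(df)
    ok = df["pos"].notna() & df["eaf"].between(0, 1, inclusive="neither")
    has_beta_se = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    has_z = df["z"].notna()
    has_p_beta = df["p"].notna() & df["beta"].notna()
    ok &= has_beta_se | has_z | has_p_beta
    ok &= ~(df["se"].notna() & (df["se"] <= 0))
    ok &= ~(df["p"].notna() & ~df["p"].between(0, 1, inclusive="right"))
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.info("%s: dropped %d malformed rows on read", path, dropped)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)

    # z reconstruction: beta/se wins over a stored (or p-derived) z when they
    # disagree beyond tolerance.
    bs = df["beta"].notna() & df["se"].notna()
    z_bs = df.loc[bs, "beta"] / df.loc[bs, "se"]
    stale = df["z"].isna()
    stale.loc[bs] |= (df.loc[bs, "z"] - z_bs).abs() > Z_CONSISTENCY_RTOL * z_bs.abs().clip(lower=1e-300)
    df.loc[bs & stale, "z"] = z_bs[stale.loc[bs]]
    # p-only path: z from the two-sided normal inverse and the sign of beta.
    need_z = df["z"].isna() & df["p"].notna() & df["beta"].notna()
    df.loc[need_z, "z"] = z_from_p(df.loc[need_z, "p"], df.loc[need_z, "beta"])
    # back-fill se and beta where reconstructable
    need_se = df["se"].isna() & df["beta"].notna() & df["z"].notna() & (df["z"] != 0)
    df.loc[need_se, "se"] = df.loc[need_se, "beta"] / df.loc[need_se, "z"]
    need_beta = df["beta"].isna() & df["z"].notna() & df["se"].notna()
    df.loc[need_beta, "beta"] = df.loc[need_beta, "z"] * df.loc[need_beta, "se"]
    # p from z where missing or inconsistent
    p_z = 2.0 * stats.norm.sf(np.abs(df["z"].to_numpy(dtype=float)))
    bad_p = df["p"].isna() | (
        np.abs(df["p"] - p_z) > Z_CONSISTENCY_RTOL * np.maximum(p_z, 1e-300)
    )
    df.loc[bad_p, "p"] = p_z[bad_p.to_numpy()]

    dup = df["variant_id"].duplicated()
    if dup.any():
        logger.info("%s: dropped %d duplicate variant ids", path, int(dup.sum()))
        dropped += int(dup.sum())
        df = df.loc[~dup].reset_index(drop=True)

    label = trait_label if trait_label is not None else str(path)
    return SumstatsTable(label, df, meta={"rows_dropped": dropped, "source": str(path)})


def write_sumstats(table: SumstatsTable, path, sep: str = "\t") -> None:
    """Write the canonical dialect (full float precision, round-trip safe)."""
    table.df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def harmonize_pair(
    a: SumstatsTable, b: SumstatsTable, remove_ambiguous: bool = False
) -> tuple[SumstatsTable, SumstatsTable]:
    """Intersect two tables on shared variants and align b's effect allele to a's.

    Variants are matched on (chrom, pos, unordered allele pair).  Where b's
    effect allele is a's other allele, b's beta and z are negated and its eaf
    complemented.  Sites with irreconcilable allele sets are dropped.  With
    ``remove_ambiguous``, strand-ambiguous (A/T, C/G) variants are removed from
    both outputs.  Outputs are sorted identically by (chrom, pos).
    """
    ka = a.key_frame().assign(_ia=np.arange(len(a.df)))
    kb = b.key_frame().assign(_ib=np.arange(len(b.df)))
    merged = ka.merge(kb, on=["chrom", "pos", "allele_lo", "allele_hi"], how="inner")
    if merged.empty:
        raise ValueError(
            f"no shared variants between '{a.trait_label}' and '{b.trait_label}'"
        )

    da = a.df.iloc[merged["_ia"].to_numpy()].reset_index(drop=True)
    db = b.df.iloc[merged["_ib"].to_numpy()].reset_index(drop=True)

    same = (db["effect_allele"].to_numpy() == da["effect_allele"].to_numpy()) & (
        db["other_allele"].to_numpy() == da["other_allele"].to_numpy()
    )
    swapped = (db["effect_allele"].to_numpy() == da["other_allele"].to_numpy()) & (
        db["other_allele"].to_numpy() == da["effect_allele"].to_numpy()
    )
    keep = same | swapped
    n_irreconcilable = int((~keep).sum())
    if n_irreconcilable:
        logger.info(
            "harmonize_pair: dropped %d variants with irreconcilable alleles",
            n_irreconcilable,
        )
    da, db, swapped = da.loc[keep], db.loc[keep], swapped[keep]

    db = db.copy()
    db.loc[swapped, "beta"] *= -1.0
    db.loc[swapped, "z"] *= -1.0
    db.loc[swapped, "eaf"] = 1.0 - db.loc[swapped, "eaf"]
    db.loc[swapped, ["effect_allele", "other_allele"]] = da.loc[
        swapped, ["effect_allele", "other_allele"]
    ].to_numpy()

    n_ambiguous = 0
    if remove_ambiguous:
        amb = _is_ambiguous(da["effect_allele"], da["other_allele"]).to_numpy()
        n_ambiguous = int(amb.sum())
        da, db = da.loc[~amb], db.loc[~amb]

    order = np.lexsort((da["pos"].to_numpy(), da["chrom"].to_numpy()))
    da = da.iloc[order].reset_index(drop=True)
    db = db.iloc[order].reset_index(drop=True)
    meta = {
        "harmonized_with": b.trait_label,
        "n_shared": len(da),
        "n_irreconcilable": n_irreconcilable,
        "n_ambiguous_removed": n_ambiguous,
    }
    return (
        SumstatsTable(a.trait_label, da, {**a.meta, **meta}),
        SumstatsTable(b.trait_label, db, {**b.meta, **meta}),
    )


def apply_qc(table: SumstatsTable, cfg: QCConfig) -> SumstatsTable:
    """Apply sample-size, region-exclusion, frequency and ambiguity filters.

    The per-filter removal counts are recorded in ``meta['qc_removed']``.
    Idempotent: a second application removes nothing.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    removed: dict[str, int] = {}

    if cfg.min_fraction_n is not None:
        if cfg.n_mode == "effective":
            nvec = table.n_eff
        else:
            nvec = df["n"] if df["n"].notna().any() else (df["n_case"] + df["n_control"])
        thresh = cfg.min_fraction_n * float(nvec.max())
        mask = nvec >= thresh
        removed["sample_size"] = int((~mask & keep).sum())
        keep &= mask

    if cfg.excluded_regions:
        in_region = pd.Series(False, index=df.index)
        chrom = df["chrom"].astype(str)
        for rchrom, start, end in cfg.excluded_regions:
            rchrom = str(rchrom).removeprefix("chr")
            in_region |= (chrom == rchrom) & df["pos"].between(start, end)
        removed["excluded_region"] = int((in_region & keep).sum())
        keep &= ~in_region

    if cfg.min_eaf > 0:
        mask = df["eaf"].between(cfg.min_eaf, 1.0 - cfg.min_eaf)
        removed["eaf"] = int((~mask & keep).sum())
        keep &= mask

    if cfg.remove_ambiguous:
        amb = _is_ambiguous(df["effect_allele"], df["other_allele"])
        removed["ambiguous"] = int((amb & keep).sum())
        keep &= ~amb

    out = df.loc[keep].reset_index(drop=True)
    logger.info("apply_qc(%s): removed %s", table.trait_label, removed)
    return SumstatsTable(
        table.trait_label, out, {**table.meta, "qc_removed": removed}
    )
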