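"""Credible sets, locus definition, cross-study consolidation, gene scores.

Fine-mapping uses single-causal-variant approximate Bayes factors (Wakefield):

    ABF_j = sqrt(se_j^2 / (se_j^2 + W^2)) * exp(z_j^2 W^2 / (2 (se_j^2 + W^2)))

with prior effect SD ``W`` (default 0.2 on the log-odds scale).  Posterior
inclusion probabilities are the normalized ABFs within a region; a credible
set is the smallest PIP-ranked subset reaching the coverage target.  Regions
without a genome-wide-significant variant yield no set; regions where the ABF
computation fails numerically fall back to a flagged single-variant set
containing the most significant variant.

Loci are defined by single-linkage merging of index variants within 1 Mb on
the same chromosome; consolidation across studies applies the same rule to the
pooled index variants, carries the union of source studies per merged locus,
and flags a locus as novel when no reference study contributed.
Gene nominations (locus x study x method -> gene) contribute 0.5 points each;
the top-scoring gene(s) per locus lead, with all genes within the tie margin
(default 1.0) of the top retained as joint candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumstatsTable

__all__ = [
    "CredibleSet",
    "abf_credible_sets",
    "define_loci",
    "consolidate_loci",
    "score_genes",
]

GENOME_WIDE_P = 5e-8


@dataclass
class CredibleSet:
    region_id: str
    variants: pd.DataFrame  # variant_id, pip, in_set (pip-sorted)
    coverage: float
    top_variant: str
    fallback_flag: bool = False

    @property
    def members(self) -> list[str]:
        return list(self.variants.loc[self.variants["in_set"], "variant_id"])


def wakefield_abf(z: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Approximate Bayes factor (association vs null) per variant.

    Computed in log space to survive large |z|.
    """
    v = se**2
    w2 = prior_sd**2
    log_abf = 0.5 * np.log(v / (v + w2)) + (z**2 / 2.0) * (w2 / (v + w2))
    return np.exp(log_abf - log_abf.max())  # normalized later; overflow-safe


def abf_credible_sets(
    region: SumstatsTable,
    prior_sd: float = 0.2,
    coverage: float = 0.95,
    sig_threshold: float = GENOME_WIDE_P,
) -> list[CredibleSet]:
    """Single-causal-variant ABF credible set for one region.

    Returns an empty list when the region is empty or carries no variant at
    genome-wide significance.  Ties on PIP break by lowest p, then smallest
    position (determinism).
    """
    df = region.df
    if len(df) == 0:
        return []
    if not (df["p"] < sig_threshold).any():
        return []

    z = df["z"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    region_id = f"{df['chrom'].iloc[0]}:{int(df['pos'].min())}-{int(df['pos'].max())}"
    abf = wakefield_abf(z, se, prior_sd)
    total = abf.sum()
    if not np.isfinite(total) or total <= 0:
        # numerical failure: artificial single-variant set, flagged
        top = df.loc[df["p"].idxmin()]
        variants = pd.DataFrame(
            {"variant_id": [top["variant_id"]], "pip": [1.0], "in_set": [True]}
        )
        return [
            CredibleSet(region_id, variants, coverage, top["variant_id"], True)
        ]

    pip = abf / total
    order = np.lexsort((df["pos"].to_numpy(), df["p"].to_numpy(), -pip))
    pip_sorted = pip[order]
    cum = np.cumsum(pip_sorted)
    n_in = int(np.searchsorted(cum, coverage) + 1)
    n_in = min(n_in, len(pip_sorted))
    variants = pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy()[order],
            "pip": pip_sorted,
            "in_set": np.arange(len(pip_sorted)) < n_in,
        }
    )
    return [
        CredibleSet(region_id, variants, coverage, variants["variant_id"].iloc[0], False)
    ]


def _merge_positions(
    chrom: np.ndarray, pos: np.ndarray, merge_distance: int
) -> np.ndarray:
    """Single-linkage cluster ids for (chrom, pos) index variants."""
    order = np.lexsort((pos, chrom))
    cluster = np.empty(len(pos), dtype=int)
    cid = -1
    prev_chrom, prev_pos = None, None
    for idx in order:
        if chrom[idx] != prev_chrom or pos[idx] - prev_pos > merge_distance:
            cid += 1
        cluster[idx] = cid
        prev_chrom, prev_pos = chrom[idx], pos[idx]
    return cluster


def define_loci(
    index_variants: pd.DataFrame, merge_distance: int = 1_000_000
) -> pd.DataFrame:
    """Merge index variants within ``merge_distance`` into non-overlapping loci.

    ``index_variants`` needs columns chrom, pos, study (and optionally
    variant_id, p).  Merging is transitive (single linkage).  The catalogue has
    one row per locus with id ``chrom:start-end``, bounds from member
    positions, member variants, and the set of contributing studies; rows are
    in genomic order and the output is deterministic under input permutation.
    """
    cols = ["locus_id", "chrom", "start", "end", "index_variants", "sources", "n_members"]
    if len(index_variants) == 0:
        return pd.DataFrame(columns=cols)
    df = index_variants.copy()
    if "variant_id" not in df:
        df["variant_id"] = (
            df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
        )
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].astype(int).to_numpy()
    df = df.assign(_cluster=_merge_positions(chrom, pos, merge_distance))

    rows = []
    for _, grp in df.groupby("_cluster"):
        start, end = int(grp["pos"].min()), int(grp["pos"].max())
        c = str(grp["chrom"].iloc[0])
        rows.append(
            {
                "locus_id": f"{c}:{start}-{end}",
                "chrom": c,
                "start": start,
                "end": end,
                "index_variants": sorted(grp["variant_id"].astype(str)),
                "sources": set(grp["study"].astype(str)) if "study" in grp else set(),
                "n_members": len(grp),
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(
        ["chrom", "start"], key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return out


def _chrom_key(c):
    try:
        return (0, int(c))
    except (TypeError, ValueError):
        return (1, str(c))


def consolidate_loci(
    catalogues: dict[str, pd.DataFrame],
    reference_studies: set[str],
    merge_distance: int = 1_000_000,
) -> pd.DataFrame:
    """Merge per-study locus catalogues into one catalogue with novelty flags.

    Index variants from all studies are pooled and re-merged by the same
    single-linkage rule; each merged locus carries the union of source studies
    and ``novel = True`` iff no reference study contributed.
    """
    frames = []
    for study, cat in catalogues.items():
        for _, row in cat.iterrows():
            for vid in row["index_variants"]:
                chrom = str(row["chrom"])
                pos = int(vid.split(":")[1]) if ":" in vid else int(row["start"])
                frames.append(
                    {"chrom": chrom, "pos": pos, "study": study, "variant_id": vid}
                )
    pooled = pd.DataFrame(frames)
    if len(pooled) == 0:
        out = pd.DataFrame(
            columns=["locus_id", "chrom", "start", "end", "index_variants", "sources", "n_members"]
        )
        out["novel"] = pd.Series(dtype=bool)
        return out
    by_vid = pooled.groupby("variant_id")["chrom"].nunique()
    clash = by_vid[by_vid > 1]
    if len(clash):
        raise ValueError(
            f"conflicting chromosome labels for index variants: {list(clash.index)}"
        )
    merged = define_loci(pooled, merge_distance)
    merged["novel"] = merged["sources"].map(
        lambda s: len(s & set(reference_studies)) == 0
    )
    return merged


def score_genes(
    nominations: pd.DataFrame,
    loci: pd.DataFrame | None = None,
    tie_margin: float = 1.0,
    points_per_nomination: float = 0.5,
) -> pd.DataFrame:
    """Aggregate gene nominations into per-locus scores and lead genes.

    ``nominations`` needs columns locus_id, study, method, gene; each
    (locus, study, method) row contributes 0.5 points to its gene, summed
    across studies and methods.  Per locus, the maximal-score gene(s) lead;
    every gene whose gap to the top score is < ``tie_margin`` is retained as a
    joint candidate.  If ``loci`` is given, nominations referencing unknown
    locus ids raise.
    """
    required = {"locus_id", "study", "method", "gene"}
    if missing := required - set(nominations.columns):
        raise ValueError(f"nominations missing columns: {sorted(missing)}")
    dup = nominations.duplicated(subset=["locus_id", "study", "method"])
    if dup.any():
        raise ValueError("duplicate (locus, study, method) nominations")
    if loci is not None:
        known = set(loci["locus_id"])
        offenders = sorted(set(nominations["locus_id"]) - known)
        if offenders:
            raise ValueError(f"nominations reference unknown loci: {offenders}")

    scores = (
        nominations.groupby(["locus_id", "gene"])
        .size()
        .mul(points_per_nomination)
        .rename("score")
        .reset_index()
    )
    leads = []
    for locus_id, grp in scores.groupby("locus_id"):
        top = grp["score"].max()
        lead_genes = sorted(grp.loc[grp["score"] > top - tie_margin, "gene"])
        leads.append({"locus_id": locus_id, "lead_genes": lead_genes, "top_score": top})
    out = scores.merge(pd.DataFrame(leads), on="locus_id")
    out["is_lead"] = [g in lg for g, lg in zip(out["gene"], out["lead_genes"])]
    return out.sort_values(["locus_id", "score"], ascending=[True, False]).reset_index(
        drop=True
    )
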