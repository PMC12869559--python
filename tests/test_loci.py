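"""Credible sets, locus merging, consolidation, gene scoring."""

import numpy as np
import pandas as pd
import pytest

from cardiocc.loci import (
    abf_credible_sets,
    consolidate_loci,
    define_loci,
    score_genes,
    wakefield_abf,
)

from conftest import make_table


class TestCredibleSets:
    def test_lone_strong_variant_single_member(self):
        t = make_table("t", beta=[0.8, 0.01, 0.02], se=[0.1, 0.1, 0.1],
                       pos=[100, 200, 300])
        sets = abf_credible_sets(t)
        assert len(sets) == 1
        cs = sets[0]
        assert cs.members == [t.df["variant_id"].iloc[0]]
        assert cs.variants["pip"].iloc[0] > 0.99
        assert not cs.fallback_flag

    def test_two_identical_variants_split_pip(self):
        t = make_table("t", beta=[0.8, 0.8], se=[0.1, 0.1], pos=[100, 200])
        sets = abf_credible_sets(t)
        cs = sets[0]
        np.testing.assert_allclose(cs.variants["pip"], [0.5, 0.5], atol=1e-12)
        assert len(cs.members) == 2

    def test_pips_match_direct_abf_normalization_oracle(self):
        rng = np.random.default_rng(3)
        z = np.concatenate([[8.0], rng.normal(0, 1.5, 9)])
        se = np.full(10, 0.08)
        t = make_table("t", beta=z * se, se=se, pos=100 * (1 + np.arange(10)))
        sets = abf_credible_sets(t, prior_sd=0.2)
        cs = sets[0]

        # direct Wakefield ABF computation, normalized brute force
        w2 = 0.2**2
        v = se**2
        abf = np.sqrt(v / (v + w2)) * np.exp(z**2 * w2 / (2 * (v + w2)))
        pip_oracle = abf / abf.sum()
        by_id = dict(zip(cs.variants["variant_id"], cs.variants["pip"]))
        for vid, pip in zip(t.df["variant_id"], pip_oracle):
            assert by_id[vid] == pytest.approx(pip, rel=1e-9)
        # pips sum to 1 within the region
        assert cs.variants["pip"].sum() == pytest.approx(1.0)

    def test_no_significant_variant_no_set(self):
        t = make_table("t", beta=[0.2, 0.1], se=[0.1, 0.1], pos=[1, 2])
        assert abf_credible_sets(t) == []

    def test_extreme_z_numerical_failure_falls_back_flagged(self):
        t = make_table("t", beta=[90.0, 60.0], se=[0.1, 0.1], pos=[1, 2])
        sets = abf_credible_sets(t)
        assert len(sets) == 1
        cs = sets[0]
        if cs.fallback_flag:
            assert len(cs.members) == 1
        else:  # survived numerically: top variant must be the stronger one
            assert cs.top_variant == t.df["variant_id"].iloc[0]


class TestDefineLoci:
    def test_within_one_mb_merged(self):
        iv = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 1_900_000], "study": ["s", "s"]}
        )
        cat = define_loci(iv)
        assert len(cat) == 1
        assert cat["locus_id"].iloc[0] == "1:1000000-1900000"

    def test_transitive_chain_single_locus(self):
        iv = pd.DataFrame(
            {"chrom": "1", "pos": [1_000_000, 1_900_000, 2_800_000], "study": "s"}
        )
        cat = define_loci(iv)
        assert len(cat) == 1  # 1.0-1.9 and 1.9-2.8 chain transitively

    def test_different_chromosomes_never_merge(self):
        iv = pd.DataFrame({"chrom": ["1", "2"], "pos": [100, 100], "study": "s"})
        assert len(define_loci(iv)) == 2

    def test_permutation_invariant_and_idempotent(self):
        rng = np.random.default_rng(5)
        iv = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2", "3"], 60),
                "pos": rng.integers(1, 30_000_000, 60),
                "study": "s",
            }
        )
        cat1 = define_loci(iv)
        cat2 = define_loci(iv.sample(frac=1, random_state=1).reset_index(drop=True))
        pd.testing.assert_frame_equal(cat1, cat2)
        # idempotence: re-merging locus midpoints changes nothing structural
        again = define_loci(
            pd.DataFrame(
                {
                    "chrom": np.repeat(cat1["chrom"], cat1["n_members"]),
                    "pos": np.concatenate(
                        [
                            [int(v.split(":")[1]) for v in members]
                            for members in cat1["index_variants"]
                        ]
                    ),
                    "study": "s",
                }
            )
        )
        assert list(again["locus_id"]) == list(cat1["locus_id"])

    def test_matches_brute_force_single_linkage_oracle(self):
        rng = np.random.default_rng(9)
        n = 80
        iv = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], n),
                "pos": rng.integers(1, 20_000_000, n),
                "study": "s",
            }
        )
        cat = define_loci(iv)

        # brute force: union-find over all pairs within 1 Mb on same chrom
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if iv.chrom[i] == iv.chrom[j] and abs(int(iv.pos[i]) - int(iv.pos[j])) <= 1_000_000:
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(n)})
        assert len(cat) == n_clusters


class TestConsolidate:
    def test_casecase_only_locus_is_novel(self):
        cc = define_loci(pd.DataFrame({"chrom": "5", "pos": [10_000_000], "study": "cc"}))
        dcm = define_loci(pd.DataFrame({"chrom": "1", "pos": [5_000_000], "study": "dcm"}))
        merged = consolidate_loci({"cc": cc, "dcm": dcm}, reference_studies={"dcm", "hcm"})
        novel = merged.set_index("chrom")["novel"]
        assert bool(novel["5"]) is True
        assert bool(novel["1"]) is False

    def test_same_variant_three_studies_one_locus(self):
        cats = {
            s: define_loci(pd.DataFrame({"chrom": "2", "pos": [7_000_000], "study": s}))
            for s in ("cc", "dcm", "hcm")
        }
        merged = consolidate_loci(cats, reference_studies={"dcm", "hcm"})
        assert len(merged) == 1
        assert merged["sources"].iloc[0] == {"cc", "dcm", "hcm"}
        assert not merged["novel"].iloc[0]

    def test_novelty_flags_match_brute_force_scan(self):
        rng = np.random.default_rng(11)
        studies = ["cc", "dcm", "hcm"]
        cats = {}
        all_iv = []
        for s in studies:
            iv = pd.DataFrame(
                {
                    "chrom": rng.choice(["1", "2", "3"], 50),
                    "pos": rng.integers(1, 60_000_000, 50),
                    "study": s,
                }
            )
            cats[s] = define_loci(iv)
            all_iv.append(iv)
        merged = consolidate_loci(cats, reference_studies={"dcm", "hcm"})
        pooled = pd.concat(all_iv, ignore_index=True)
        for _, locus in merged.iterrows():
            # brute force membership scan over the pooled index variants
            inside = pooled[
                (pooled.chrom == locus.chrom)
                & (pooled.pos >= locus.start)
                & (pooled.pos <= locus.end)
            ]
            expect_novel = not inside.study.isin({"dcm", "hcm"}).any()
            assert bool(locus.novel) == expect_novel

    def test_conflicting_chromosomes_hard_error(self):
        c1 = define_loci(pd.DataFrame({"chrom": "1", "pos": [100], "study": "a"}))
        c2 = c1.copy()
        c2["chrom"] = "2"
        with pytest.raises(ValueError, match="conflicting chromosome"):
            consolidate_loci({"a": c1, "b": c2}, reference_studies=set())


class TestGeneScores:
    def test_worked_example_two_studies_two_methods(self):
        nom = pd.DataFrame(
            [
                ("L12", "dcm_mtag", "pops", "DTL"),
                ("L12", "dcm_mtag", "flames", "DTL"),
                ("L12", "cc_mtag", "pops", "BATF3"),
                ("L12", "cc_mtag", "flames", "DTL"),
            ],
            columns=["locus_id", "study", "method", "gene"],
        )
        out = score_genes(nom)
        scores = out.set_index("gene")["score"]
        assert scores["DTL"] == 1.5
        assert scores["BATF3"] == 0.5
        assert out.loc[out["gene"] == "DTL", "is_lead"].all()
        assert not out.loc[out["gene"] == "BATF3", "is_lead"].any()

    def test_tied_genes_joint_leads(self):
        nom = pd.DataFrame(
            [
                ("L1", "s1", "pops", "X"),
                ("L1", "s1", "flames", "Y"),
                ("L1", "s2", "pops", "X"),
                ("L1", "s2", "flames", "Y"),
            ],
            columns=["locus_id", "study", "method", "gene"],
        )
        out = score_genes(nom)
        assert set(out["lead_genes"].iloc[0]) == {"X", "Y"}
        assert out["is_lead"].all()

    def test_single_nomination_sole_lead(self):
        nom = pd.DataFrame(
            [("L1", "s1", "pops", "X")], columns=["locus_id", "study", "method", "gene"]
        )
        out = score_genes(nom)
        assert out["score"].iloc[0] == 0.5
        assert out["lead_genes"].iloc[0] == ["X"]

    def test_score_mass_conserved(self):
        rng = np.random.default_rng(13)
        rows = [
            (f"L{rng.integers(5)}", f"s{i%3}", m, rng.choice(list("ABCD")))
            for i, m in enumerate(["pops", "flames"] * 30)
        ]
        nom = pd.DataFrame(rows, columns=["locus_id", "study", "method", "gene"])
        nom = nom.drop_duplicates(subset=["locus_id", "study", "method"])
        out = score_genes(nom)
        assert out["score"].sum() == pytest.approx(0.5 * len(nom))

    def test_unknown_locus_rejected(self):
        nom = pd.DataFrame(
            [("Lmissing", "s1", "pops", "X")],
            columns=["locus_id", "study", "method", "gene"],
        )
        loci = pd.DataFrame({"locus_id": ["L1"]})
        with pytest.raises(ValueError, match="Lmissing"):
            score_genes(nom, loci=loci)
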