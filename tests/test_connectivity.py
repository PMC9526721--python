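from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import sigscreen as ss
from sigscreen.errors import FormatError, InsufficientDataError

from conftest import ks_oracle

GENES = [f"g{i + 1}" for i in range(10)]


def profile_from_ranks(ranks, genes=None, instance="i1", compound="c1"):
    genes = genes or [f"g{i + 1}" for i in range(len(ranks))]
    return ss.RankedProfile(instance, compound, pd.Series(ranks, index=genes))


class TestKsTagStatistic:
    def test_top_ranked_tags(self):
        prof = profile_from_ranks(range(1, 11))
        assert ss.ks_tag_statistic(["g1", "g2"], prof) == pytest.approx(0.8)

    def test_bottom_ranked_tags(self):
        prof = profile_from_ranks(range(1, 11))
        assert ss.ks_tag_statistic(["g9", "g10"], prof) == pytest.approx(-0.9)

    def test_matches_exhaustive_oracle(self):
        # every placement of t tags in a profile of n genes, n <= 8, t <= 4
        for n in range(2, 9):
            genes = [f"g{i + 1}" for i in range(n)]
            prof = profile_from_ranks(range(1, n + 1), genes)
            for t in range(1, min(4, n - 1) + 1):
                for pos in combinations(range(1, n + 1), t):
                    tags = [genes[p - 1] for p in pos]
                    assert ss.ks_tag_statistic(tags, prof) == pytest.approx(
                        ks_oracle(pos, n), abs=1e-12
                    ), (n, pos)

    def test_tag_outside_universe(self):
        prof = profile_from_ranks(range(1, 11))
        with pytest.raises(KeyError):
            ss.ks_tag_statistic(["nope"], prof)

    def test_whole_universe_rejected(self):
        prof = profile_from_ranks(range(1, 11))
        with pytest.raises(ValueError):
            ss.ks_tag_statistic(GENES, prof)


class TestInstanceRawScore:
    def test_opposite_signs_subtract(self):
        prof = profile_from_ranks(range(1, 11))
        s = ss.instance_raw_score(["g1", "g2"], ["g9", "g10"], prof)
        assert s == pytest.approx(0.8 - (-0.9))

    def test_same_sign_is_null(self):
        prof = profile_from_ranks(range(1, 11))
        # both tag sets near the top: both KS statistics positive
        s = ss.instance_raw_score(["g1", "g2"], ["g3", "g4"], prof)
        assert s == 0.0

    def test_concordant_placement_is_maximal(self):
        # for n = 8, |up| = |down| = 2: the top/bottom placement beats every
        # other disjoint placement (exhaustive check)
        n = 8
        genes = [f"g{i + 1}" for i in range(n)]
        prof = profile_from_ranks(range(1, n + 1), genes)
        best = max(
            ss.instance_raw_score([genes[i] for i in up], [genes[j] for j in dn], prof)
            for up in combinations(range(n), 2)
            for dn in combinations(range(n), 2)
            if not set(up) & set(dn)
        )
        concordant = ss.instance_raw_score(["g1", "g2"], ["g7", "g8"], prof)
        assert concordant == pytest.approx(best)
        assert concordant > 0

    def test_overlapping_tags_rejected(self):
        prof = profile_from_ranks(range(1, 11))
        with pytest.raises(FormatError):
            ss.instance_raw_score(["g1"], ["g1"], prof)


class TestScaling:
    def test_arithmetic_example(self):
        scaled = ss.scale_connectivity_scores([1.7, -0.85, 0.34])
        np.testing.assert_allclose(scaled, [1.0, -1.0, 0.2])

    def test_single_positive_instance(self):
        np.testing.assert_allclose(ss.scale_connectivity_scores([0.4]), [1.0])

    def test_all_zero(self):
        np.testing.assert_allclose(ss.scale_connectivity_scores([0.0, 0.0]), [0.0, 0.0])

    def test_invariant_to_positive_rescaling(self, rng):
        raw = rng.normal(size=20)
        a = ss.scale_connectivity_scores(raw)
        b = ss.scale_connectivity_scores(3.7 * raw)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_extremes_hit_plus_minus_one(self, rng):
        raw = rng.normal(size=15)
        scaled = ss.scale_connectivity_scores(raw)
        assert scaled.max() == pytest.approx(1.0)
        assert scaled.min() == pytest.approx(-1.0)
        assert np.all(np.abs(scaled) <= 1.0)


class TestCompoundStatistics:
    def test_mean_per_compound(self):
        scaled = pd.Series({"a.1": 1.0, "a.2": 0.5, "b.1": -0.3})
        ranks = pd.DataFrame(
            {inst: np.random.default_rng(i).permutation(np.arange(1, 7))
             for i, inst in enumerate(["a.1", "a.2", "b.1"])},
            index=[f"g{i}" for i in range(6)],
        )
        comp = ss.ReferenceCompendium(
            ranks, pd.DataFrame({"instance_id": ["a.1", "a.2", "b.1"],
                                 "compound": ["a", "a", "b"]}))
        means = ss.compound_summary(scaled, comp)
        assert means["a"] == pytest.approx(0.75)
        assert means["b"] == pytest.approx(-0.3)

    def test_percent_nonnull(self):
        assert ss.percent_nonnull([0.9, 0.2, 0.0, -0.1], 0.25) == pytest.approx(50.0)
        assert ss.percent_nonnull([0.3, 0.8], 0.55) == pytest.approx(100.0)
        assert ss.percent_nonnull([0.5, -0.5], 0.0) == 0.0


def build_compendium(seed=0, n_genes=60, compounds=("a", "b", "c"), instances=3):
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    cols, meta = {}, []
    for c in compounds:
        for i in range(instances):
            inst = f"{c}.{i + 1}"
            order = rng.permutation(n_genes)
            ranks = np.empty(n_genes, dtype=int)
            ranks[order] = np.arange(1, n_genes + 1)
            cols[inst] = ranks
            meta.append((inst, c))
    return ss.ReferenceCompendium(pd.DataFrame(cols, index=genes),
                                  pd.DataFrame(meta, columns=["instance_id", "compound"]))


class TestPermutationPvalue:
    def test_add_one_formula_floor(self):
        comp = build_compendium(compounds=tuple("abcdefgh"))
        genes = comp.universe
        # make every instance of compound "a" perfectly concordant (distinct
        # fillers between the tag blocks): the observed mean scaled score is
        # 1.0, which random-tag nulls cannot tie -> p sits at the add-one floor
        ranks = comp.ranks.copy()
        up, down = genes[:5], genes[-5:]
        rest = np.array([g for g in genes if g not in set(up) | set(down)])
        rng = np.random.default_rng(2)
        for inst in comp.compound_instances("a"):
            ordered = list(up) + list(rng.permutation(rest)) + list(down)
            ranks[inst] = pd.Series({g: i + 1 for i, g in enumerate(ordered)})
        comp2 = ss.ReferenceCompendium(ranks, comp.meta)
        sig = ss.QuerySignature(list(up), list(down))
        p = ss.permutation_pvalue("a", sig, comp2, B=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_reproducible_given_seed(self):
        comp = build_compendium(seed=3)
        sig = ss.QuerySignature(comp.universe[:4], comp.universe[4:8])
        p1 = ss.permutation_pvalue("b", sig, comp, B=50, seed=42)
        p2 = ss.permutation_pvalue("b", sig, comp, B=50, seed=42)
        assert p1 == p2

    def test_universe_too_small(self):
        # a signature built on a larger gene space than the compendium: the
        # null cannot draw disjoint tag sets of the requested sizes
        comp = build_compendium(n_genes=6)
        big = [f"x{i}" for i in range(10)]
        sig = ss.QuerySignature(big[:5], big[5:])
        with pytest.raises(InsufficientDataError):
            ss.permutation_pvalues(sig, comp,
                                   pd.Series(0.0, index=comp.compounds),
                                   B=10, seed=0)


class TestSpecificity:
    def test_observed_stronger_than_all_decoys(self, rng):
        comp = build_compendium(seed=5, compounds=tuple("abcdefgh"))
        genes = comp.universe
        ranks = comp.ranks.copy()
        up, down = genes[:5], genes[-5:]
        rest = np.array([g for g in genes if g not in set(up) | set(down)])
        shuffler = np.random.default_rng(4)
        for inst in comp.compound_instances("a"):
            ordered = list(up) + list(shuffler.permutation(rest)) + list(down)
            ranks[inst] = pd.Series({g: i + 1 for i, g in enumerate(ordered)})
        comp2 = ss.ReferenceCompendium(ranks, comp.meta)
        sig = ss.QuerySignature(list(up), list(down))
        decoys = [ss.random_signature(genes, 5, 5, rng) for _ in range(20)]
        spec = ss.specificity_score("a", sig, decoys, comp2)
        assert spec <= 0.05

    def test_zero_observed_score_gives_one(self, rng):
        comp = build_compendium(seed=6)
        sig = ss.QuerySignature(comp.universe[:4], comp.universe[4:8])
        report = ss.score_compendium(sig, comp, B=10, seed=0)
        # pick a compound with mean exactly 0 if present; otherwise craft one
        decoys = [ss.random_signature(comp.universe, 4, 4, rng) for _ in range(5)]
        zero = report.compounds.index[report.compounds["mean_score"] == 0]
        if len(zero):
            assert ss.specificity_score(zero[0], sig, decoys, comp) == 1.0

    def test_empty_decoys_rejected(self):
        comp = build_compendium()
        sig = ss.QuerySignature(comp.universe[:4], comp.universe[4:8])
        with pytest.raises(InsufficientDataError):
            ss.specificity_score("a", sig, [], comp)


class TestRanking:
    def test_sorted_by_p_then_mean(self):
        table = pd.DataFrame(
            {"mean_score": [0.3, 0.9, 0.9], "p_perm": [0.2, 0.01, 0.01],
             "percent_nonnull": [0.0, 0.0, 0.0]},
            index=["x", "b", "a"])
        ranked = ss.rank_small_molecules(table)
        assert list(ranked.index) == ["a", "b", "x"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_tie_on_p_prefers_larger_mean(self):
        table = pd.DataFrame(
            {"mean_score": [0.3, 0.9], "p_perm": [0.05, 0.05],
             "percent_nonnull": [0.0, 0.0]},
            index=["weak", "strong"])
        ranked = ss.rank_small_molecules(table)
        assert list(ranked.index) == ["strong", "weak"]


class TestCompendiumIO:
    def test_round_trip(self, tmp_path):
        comp = build_compendium(seed=9)
        ss.write_compendium(comp, tmp_path / "r.tsv", tmp_path / "m.tsv")
        back = ss.read_compendium(tmp_path / "r.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.ranks, comp.ranks, check_dtype=False)
        assert list(back.meta["compound"]) == list(comp.meta["compound"])

    def test_invalid_ranks_rejected(self):
        genes = ["g1", "g2", "g3"]
        ranks = pd.DataFrame({"i1": [1, 1, 3]}, index=genes)
        with pytest.raises(FormatError):
            ss.ReferenceCompendium(ranks, pd.DataFrame({"instance_id": ["i1"],
                                                        "compound": ["c"]}))

    def test_tie_breaking_ingest(self, tmp_path):
        genes = ["g1", "g2", "g3"]
        pd.DataFrame({"i1": [0.5, 0.5, 2.0]}, index=genes).to_csv(
            tmp_path / "r.tsv", sep="\t", index_label="gene")
        pd.DataFrame({"instance_id": ["i1"], "compound": ["c"]}).to_csv(
            tmp_path / "m.tsv", sep="\t", index=False)
        comp = ss.read_compendium(tmp_path / "r.tsv", tmp_path / "m.tsv",
                                  break_ties=True)
        assert sorted(comp.ranks["i1"]) == [1, 2, 3]


class TestProfileReversal:
    def test_reversed_profile_scores_minus_one_with_scaling(self):
        # a perfectly concordant instance and its rank-reversed twin inside
        # one compendium: after scaling they sit at exactly +1 and -1
        n = 40
        genes = [f"g{i + 1}" for i in range(n)]
        up, down = genes[:4], genes[-4:]
        rest = genes[4:-4]
        fwd_order = list(up) + rest + list(down)
        fwd = {g: i + 1 for i, g in enumerate(fwd_order)}
        rev = {g: n + 1 - r for g, r in fwd.items()}
        rng = np.random.default_rng(0)
        cols = {"fwd.1": pd.Series(fwd), "rev.1": pd.Series(rev)}
        for i in range(3):
            order = rng.permutation(n)
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            cols[f"r{i}.1"] = pd.Series(ranks, index=genes)
        comp = ss.ReferenceCompendium(
            pd.DataFrame(cols, index=genes),
            pd.DataFrame({"instance_id": list(cols),
                          "compound": [c.split(".")[0] for c in cols]}))
        sig = ss.QuerySignature(list(up), list(down))
        report = ss.score_compendium(sig, comp, B=20, seed=0)
        inst = report.instances.set_index("instance_id")
        assert inst.loc["fwd.1", "scaled"] == pytest.approx(1.0)
        assert inst.loc["rev.1", "scaled"] == pytest.approx(-1.0)
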