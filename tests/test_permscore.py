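import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from tcmis.genesets import GeneSet
from tcmis.permscore import (
    CompoundTargetProfile,
    NullSampler,
    ScoreSettings,
    analytic_pvalue,
    combine_models,
    eligible_profiles,
    permutation_pvalue,
    permutation_zscore,
    profiles_from_ct_edges,
    sample_null,
    score_model,
)
from tcmis.stats_core import DomainError

from conftest import enum_hypergeom_tail


def profile(cid, *targets):
    return CompoundTargetProfile(compound_id=cid, targets=frozenset(targets))


def geneset(*genes):
    return GeneSet("GS", frozenset(genes))


class TestEligibility:
    def test_zero_overlap_excluded(self):
        kept = eligible_profiles([profile("c", "x")], geneset("y"))
        assert kept == []

    def test_blocklisted_excluded(self):
        kept = eligible_profiles(
            [profile("ion", "y")], geneset("y"), blocklist={"ion"}
        )
        assert kept == []

    def test_single_member_target_retained(self):
        kept = eligible_profiles([profile("c", "y", "z")], geneset("y"))
        assert [p.compound_id for p in kept] == ["c"]

    def test_empty_profile_rejected(self):
        with pytest.raises(DomainError):
            profile("c")


class TestNullSampler:
    def test_full_universe_draws_everything(self):
        sampler = sample_null(5, universe_size=5, n_permutations=50, seed=1)
        overlaps = sampler.overlaps([0, 2, 4])
        assert (overlaps == 3).all()

    def test_empty_geneset_zero_overlap(self):
        sampler = sample_null(0, universe_size=5, n_permutations=10, seed=1)
        assert (sampler.overlaps([0, 1]) == 0).all()

    def test_draws_are_distinct_genes(self):
        sampler = sample_null(4, universe_size=10, n_permutations=200, seed=2)
        for row in sampler._draws[:20]:
            assert len(set(row.tolist())) == 4

    def test_matches_hypergeometric_distribution(self):
        # overlap for (universe 10, x 4, m 3) ~ Hypergeom(10, 3, 4)
        n = 100_000
        sampler = sample_null(4, universe_size=10, n_permutations=n, seed=3)
        overlaps = sampler.overlaps([0, 1, 2])
        for k in range(4):
            expected = hypergeom.pmf(k, 10, 3, 4)
            se = math.sqrt(expected * (1 - expected) / n)
            observed = (overlaps == k).mean()
            assert abs(observed - expected) <= 3 * se + 1e-12

    def test_loop_path_matches_shape(self):
        # universe large enough to take the per-row sampling path
        sampler = NullSampler(3, universe_size=300_000, n_permutations=80, seed=4)
        assert sampler._draws.shape == (80, 3)
        assert (sampler._draws < 300_000).all()
        overlaps = sampler.overlaps([0, 1, 2])
        assert overlaps.shape == (80,)

    def test_oversized_geneset_rejected(self):
        with pytest.raises(DomainError):
            sample_null(11, universe_size=10, n_permutations=5, seed=0)


class TestPermutationStats:
    def test_p_zero_when_observed_at_max(self):
        assert permutation_pvalue(5, np.array([1, 2, 5])) == 0.0

    def test_p_one_when_below_min_no_ties(self):
        assert permutation_pvalue(0, np.array([1, 2, 3])) == 1.0

    def test_analytic_example(self):
        # (universe 10, x 4, m 3): P(X > 2) = P(X = 3) = 1/30
        p = analytic_pvalue(2, m=3, geneset_size=4, universe_size=10)
        assert math.isclose(p, 1 / 30, abs_tol=1e-12)
        assert math.isclose(p, enum_hypergeom_tail(10, 4, 3, 2, strict=True), abs_tol=1e-12)

    def test_mc_converges_to_analytic(self):
        n = 100_000
        sampler = sample_null(4, universe_size=10, n_permutations=n, seed=5)
        overlaps = sampler.overlaps([0, 1, 2])
        p_hat = permutation_pvalue(2, overlaps)
        p = analytic_pvalue(2, 3, 4, 10)
        assert abs(p_hat - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_zscore_example(self):
        # closed form: mean 1.2, variance 0.56 -> Z(obs 3) = 2.405
        n = 100_000
        sampler = sample_null(4, universe_size=10, n_permutations=n, seed=6)
        overlaps = sampler.overlaps([0, 1, 2])
        z = permutation_zscore(3, overlaps)
        assert abs(z - (3 - 1.2) / math.sqrt(0.56)) < 0.05

    def test_zscore_zero_at_mean(self):
        nulls = np.array([1, 2, 3, 2])
        assert permutation_zscore(2, nulls) == 0.0

    def test_zscore_monotone_in_observed(self):
        nulls = np.array([0, 1, 2, 1, 0])
        zs = [permutation_zscore(k, nulls) for k in range(4)]
        assert zs == sorted(zs)

    def test_degenerate_null_raises(self):
        with pytest.raises(DomainError):
            permutation_zscore(1, np.array([2, 2, 2]))

    def test_strict_vs_nonstrict_identity(self):
        from tcmis.stats_core import TailProblem, hypergeom_tail

        p_strict = analytic_pvalue(2, 3, 4, 10)
        p_loose = hypergeom_tail(TailProblem(10, 4, 3, 2))
        assert math.isclose(p_loose - p_strict, hypergeom.pmf(2, 10, 4, 3), abs_tol=1e-12)

    def test_mc_vs_analytic_many_random_configs(self, rng):
        n = 20_000
        ok = 0
        trials = 25
        for _ in range(trials):
            universe = int(rng.integers(8, 40))
            x = int(rng.integers(1, universe))
            m = int(rng.integers(1, min(8, universe)))
            observed = int(rng.integers(0, min(m, x) + 1))
            sampler = NullSampler(x, universe, n, seed=int(rng.integers(1 << 30)))
            overlaps = sampler.overlaps(list(range(m)))
            p_hat = permutation_pvalue(observed, overlaps)
            p = analytic_pvalue(observed, m, x, universe)
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            if abs(p_hat - p) <= 3 * se + 1e-9:
                ok += 1
        assert ok >= 0.9 * trials


class TestScoreModel:
    def _small_model(self, method, seed=0):
        genes = geneset(*(str(i) for i in range(5)))
        profiles = [
            profile("hit", "0", "1", "2"),
            profile("miss", "0", "40", "41"),
            profile("null", "42", "43"),  # ineligible: no overlap
        ]
        settings = ScoreSettings(
            universe_size=50, n_permutations=4000, seed=seed, method=method
        )
        return score_model(profiles, genes, settings)

    @pytest.mark.parametrize("method", ["permutation", "analytic"])
    def test_ineligible_dropped(self, method):
        model = self._small_model(method)
        assert {r.compound_id for r in model.results} == {"hit", "miss"}

    def test_identical_profiles_share_pvalue(self):
        genes = geneset("0", "1")
        profiles = [profile(f"c{i}", "0", "9") for i in range(4)]
        model = score_model(
            profiles, genes, ScoreSettings(universe_size=30, n_permutations=500, seed=1)
        )
        assert len({r.pvalue for r in model.results}) == 1
        assert len({r.qvalue for r in model.results}) == 1

    def test_bit_reproducible_given_seed(self):
        m1 = self._small_model("permutation", seed=11)
        m2 = self._small_model("permutation", seed=11)
        assert m1.results == m2.results
        assert m1.positives == m2.positives

    def test_analytic_matches_closed_form(self):
        model = self._small_model("analytic")
        hit = next(r for r in model.results if r.compound_id == "hit")
        assert hit.observed_overlap == 3
        assert hit.pvalue == pytest.approx(analytic_pvalue(3, 3, 5, 50))
        mean = 3 * 5 / 50
        var = 3 * (5 / 50) * (45 / 50) * (47 / 49)
        assert hit.null_mean == pytest.approx(mean)
        assert hit.zscore == pytest.approx((3 - mean) / math.sqrt(var))

    def test_positives_antitone_in_q_threshold(self):
        genes = geneset(*(str(i) for i in range(5)))
        profiles = [profile("hit", "0", "1", "2"), profile("miss", "0", "40", "41")]
        loose = score_model(
            profiles, genes, ScoreSettings(universe_size=50, method="analytic", q_threshold=0.5)
        )
        tight = score_model(
            profiles, genes, ScoreSettings(universe_size=50, method="analytic", q_threshold=1e-6)
        )
        assert tight.positives <= loose.positives

    def test_planted_recovery_small(self, rng):
        # 20 planted members-heavy compounds among 100 under one model
        from tcmis import hct_network, synthetic
        from tcmis.genesets import union_sets

        cfg = synthetic.SyntheticConfig(
            seed=42, n_compounds=100, planted_positive_fraction=0.2,
            planted_cir_bias=5.0, targets_per_compound=(6, 6),
        )
        cir = synthetic.make_cir_sets(cfg)
        data = synthetic.make_hct(cfg, cir)
        edges = [
            hct_network.classify_direct(r["compound_id"], r["entrez_id"])
            for r in data.ct_rows
        ]
        profiles = profiles_from_ct_edges(hct_network.dedupe_ct(edges))
        model = score_model(
            profiles, union_sets(cir),
            ScoreSettings(n_permutations=2000, seed=42),
        )
        recovered = model.positives & data.planted_positives
        assert len(recovered) >= 18


class TestCombineModels:
    def test_no_models_raises(self):
        with pytest.raises(DomainError):
            combine_models([])

    def test_single_model_intersection_equals_union(self):
        genes = geneset(*(str(i) for i in range(5)))
        profiles = [profile("hit", "0", "1", "2"), profile("miss", "0", "40", "41")]
        model = score_model(profiles, genes, ScoreSettings(universe_size=50, method="analytic"))
        consensus = combine_models([model])
        assert consensus.union_positives == model.positives
        assert consensus.all_model_positives == model.positives
        zs = np.array([r.zscore for r in model.results])
        expected = (zs - zs.mean()) / zs.std()
        for r, e in zip(model.results, expected):
            assert consensus.combined_z[r.compound_id] == pytest.approx(e)

    def test_minmax_normalization_bounds(self):
        genes = geneset(*(str(i) for i in range(5)))
        profiles = [
            profile("a", "0", "1", "2"),
            profile("b", "0", "40", "41"),
            profile("c", "1", "39", "38"),
        ]
        model = score_model(profiles, genes, ScoreSettings(universe_size=50, method="analytic"))
        consensus = combine_models([model], normalization="minmax")
        values = list(consensus.combined_z.values())
        assert min(values) == pytest.approx(0.0)
        assert max(values) == pytest.approx(1.0)

    def test_compound_scored_in_subset_of_models(self):
        gs_a = GeneSet("A", frozenset({"0", "1", "2"}))
        gs_b = GeneSet("B", frozenset({"7", "8"}))
        profiles = [profile("both", "0", "7"), profile("only_a", "1", "20")]
        settings = ScoreSettings(universe_size=40, method="analytic")
        model_a = score_model(profiles, gs_a, settings)
        model_b = score_model(profiles, gs_b, settings)
        consensus = combine_models([model_a, model_b])
        assert "only_a" in consensus.combined_z
        assert "both" in consensus.combined_z
        # intersection counts only models in which the compound was scored
        if "only_a" in model_a.positives:
            assert "only_a" in consensus.all_model_positives

    def test_top_ranking_enriched_for_planted(self):
        from tcmis import hct_network, synthetic
        from tcmis.genesets import union_sets, integrate_min_membership

        cfg = synthetic.SyntheticConfig(
            seed=9, n_compounds=150, planted_positive_fraction=0.2,
            planted_cir_bias=5.0, targets_per_compound=(6, 6),
        )
        cir = synthetic.make_cir_sets(cfg)
        data = synthetic.make_hct(cfg, cir)
        edges = [
            hct_network.classify_direct(r["compound_id"], r["entrez_id"])
            for r in data.ct_rows
        ]
        profiles = profiles_from_ct_edges(hct_network.dedupe_ct(edges))
        models = []
        roster = list(cir.sets) + [
            integrate_min_membership(cir, 2, "IG-1"), union_sets(cir, "IG-2")
        ]
        for gs in roster:
            models.append(
                score_model(profiles, gs, ScoreSettings(method="analytic"))
            )
        consensus = combine_models(models)
        ranked = [cid for cid, _ in consensus.ranked()]
        top = set(ranked[: max(1, len(ranked) // 10)])
        planted_rate = len(data.planted_positives) / cfg.n_compounds
        top_rate = len(top & data.planted_positives) / len(top)
        assert top_rate >= 5 * planted_rate


class TestProfilesFromEdges:
    def test_collapse(self):
        from tcmis.hct_network import classify_direct

        edges = [
            classify_direct("c1", "t1"),
            classify_direct("c1", "t2"),
            classify_direct("c2", "t1"),
        ]
        profiles = profiles_from_ct_edges(edges)
        assert {p.compound_id: p.targets for p in profiles} == {
            "c1": {"t1", "t2"},
            "c2": {"t1"},
        }
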