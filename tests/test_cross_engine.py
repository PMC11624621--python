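"""Tests for virtual Mendelian crosses, with a brute-force gamete-pair
enumeration oracle for the expectation engine."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loadtune import (
    CrossSpec,
    DominanceModel,
    Individual,
    Population,
    Variant,
    all_cross_results,
    cross_loads_frame,
    enumerate_crosses,
    expected_offspring_profile,
    profile_from_cross_loads,
    read_cross_loads,
    sample_offspring,
    shared_load,
    shared_load_matrix,
    transmission_prob,
    write_cross_loads,
)
from loadtune.load_model import per_scaffold_load, realised_contribution, scaffold_order


def brute_force_expected_profile(cross, population, model):
    """Independent oracle: per locus, enumerate the four equiprobable
    gamete pairs and average the realised contribution."""
    a = population.individual(cross.parent_a)
    b = population.individual(cross.parent_b)
    order = scaffold_order(population.variants)
    scores = np.zeros(len(order))
    for v in population.variants:
        da, db = a.dosage(v.variant_id), b.dosage(v.variant_id)
        if da is None or db is None:
            continue
        gametes_a = [1] * da + [0] * (2 - da)
        gametes_b = [1] * db + [0] * (2 - db)
        contribs = [
            realised_contribution(v, ga + gb, model)
            for ga, gb in itertools.product(gametes_a, gametes_b)
        ]
        scores[order.index(v.scaffold)] += np.mean(contribs)
    return scores


class TestTransmission:
    @pytest.mark.parametrize("dosage, prob", [(0, 0.0), (1, 0.5), (2, 1.0)])
    def test_mendelian_probabilities(self, dosage, prob):
        assert transmission_prob(dosage) == prob

    def test_invalid_dosage(self):
        with pytest.raises(ValueError):
            transmission_prob(3)


class TestEnumeration:
    def test_six_founders_give_36_ordered_crosses(self):
        crosses = enumerate_crosses([f"PP{i}" for i in range(1, 7)])
        assert len(crosses) == 36
        assert len({c.cross_id for c in crosses}) == 36

    def test_single_individual_selfing_only(self):
        (cross,) = enumerate_crosses(["A"])
        assert cross.is_selfing

    def test_three_individuals_explicit_listing(self):
        crosses = enumerate_crosses(["b", "a", "c"])
        expected = [
            ("a", "a"), ("a", "b"), ("a", "c"),
            ("b", "a"), ("b", "b"), ("b", "c"),
            ("c", "a"), ("c", "b"), ("c", "c"),
        ]
        assert [(c.parent_a, c.parent_b) for c in crosses] == expected
        assert sum(c.is_selfing for c in crosses) == 3

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            enumerate_crosses([])


class TestExpectedProfile:
    def test_two_heterozygotes_quarter_homozygous(self):
        pop = Population(
            variants=[Variant("v", "s", 1, 4.0)],
            individuals=[Individual("A", {"v": 1}), Individual("B", {"v": 1})],
        )
        result = expected_offspring_profile(CrossSpec("A", "B"), pop)
        assert result.total == pytest.approx(1.0)  # P(hom) = 1/4

    def test_fixed_parents_guarantee_homozygote(self):
        pop = Population(
            variants=[Variant("v", "s", 1, 9.5)],
            individuals=[Individual("A", {"v": 2}), Individual("B", {"v": 2})],
        )
        assert expected_offspring_profile(CrossSpec("A", "B"), pop).total == pytest.approx(9.5)

    def test_het_by_noncarrier_cannot_be_homozygous(self):
        pop = Population(
            variants=[Variant("v", "s", 1, 4.0)],
            individuals=[Individual("A", {"v": 1}), Individual("B", {"v": 0})],
        )
        assert expected_offspring_profile(CrossSpec("A", "B"), pop).total == 0.0

    def test_unknown_parent_rejected(self, tiny_population):
        with pytest.raises(KeyError):
            expected_offspring_profile(CrossSpec("X", "nobody"), tiny_population)

    def test_symmetry(self, tiny_population):
        ab = expected_offspring_profile(CrossSpec("X", "Y"), tiny_population)
        ba = expected_offspring_profile(CrossSpec("Y", "X"), tiny_population)
        np.testing.assert_allclose(ab.profile.scores, ba.profile.scores)

    def test_selfing_closed_form(self, tiny_population):
        """For h=0 the selfing expectation is exactly sum(score * p^2)."""
        for ind_id in tiny_population.individual_ids:
            ind = tiny_population.individual(ind_id)
            result = expected_offspring_profile(CrossSpec(ind_id, ind_id), tiny_population)
            closed = sum(
                v.impact_score * transmission_prob(ind.dosage(v.variant_id)) ** 2
                for v in tiny_population.variants
            )
            assert result.total == pytest.approx(closed, abs=1e-12)

    def test_total_equals_profile_sum(self, default_population):
        result = expected_offspring_profile(CrossSpec("PP1", "PP2"), default_population)
        assert result.total == pytest.approx(float(result.profile.scores.sum()))


@settings(deadline=None, max_examples=80)
@given(
    dosages=st.lists(
        st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=20
    ),
    scores=st.data(),
    h=st.sampled_from([0.0, 0.1, 0.5, 1.0]),
    selfing=st.booleans(),
)
def test_expectation_matches_gamete_enumeration_oracle(dosages, scores, h, selfing):
    """The closed-form expectation agrees with brute-force enumeration of
    the <= 4 equiprobable gamete pairs per locus, to 1e-12."""
    score_list = scores.draw(
        st.lists(
            st.floats(min_value=0, max_value=300, allow_nan=False),
            min_size=len(dosages),
            max_size=len(dosages),
        )
    )
    variants = [
        Variant(f"v{i}", f"s{i % 3}", i + 1, s) for i, s in enumerate(score_list)
    ]
    a = Individual("A", {f"v{i}": da for i, (da, _) in enumerate(dosages)})
    b = Individual("B", {f"v{i}": (da if selfing else db)
                         for i, (da, db) in enumerate(dosages)})
    if selfing:
        b = Individual("A2", dict(a.genotypes))
    pop = Population(variants=variants, individuals=[a, b])
    model = DominanceModel(h=h)
    cross = CrossSpec("A", "A" if selfing else "B")
    result = expected_offspring_profile(cross, pop, model)
    oracle = brute_force_expected_profile(cross, pop, model)
    np.testing.assert_allclose(result.profile.scores, oracle, atol=1e-12, rtol=1e-12)


class TestSampling:
    def test_fixed_parents_always_homozygous(self):
        pop = Population(
            variants=[Variant("v", "s", 1, 4.0)],
            individuals=[Individual("A", {"v": 2})],
        )
        for seed in range(5):
            child = sample_offspring(CrossSpec("A", "A"), pop, seed=seed)
            assert child.dosage("v") == 2

    def test_same_seed_identical_offspring(self, tiny_population):
        c1 = sample_offspring(CrossSpec("X", "Y"), tiny_population, seed=11)
        c2 = sample_offspring(CrossSpec("X", "Y"), tiny_population, seed=11)
        assert c1.genotypes == c2.genotypes

    def test_selfing_heterozygote_quarter_homozygous(self):
        pop = Population(
            variants=[Variant("v", "s", 1, 1.0)],
            individuals=[Individual("A", {"v": 1})],
        )
        n = 10_000
        hom = sum(
            sample_offspring(CrossSpec("A", "A"), pop, seed=s).dosage("v") == 2
            for s in range(n)
        )
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(hom / n - 0.25) < 3 * se

    def test_sampled_mean_load_converges_to_expectation(self, tiny_population):
        """Monte-Carlo offspring realised loads average to the closed-form
        expectation within 3 standard errors at N=10,000."""
        cross = CrossSpec("X", "Y")
        expected = expected_offspring_profile(cross, tiny_population).total
        n = 10_000
        totals = np.empty(n)
        for s in range(n):
            child = sample_offspring(cross, tiny_population, seed=s)
            totals[s] = per_scaffold_load(child, tiny_population.variants).total
        se = totals.std(ddof=1) / np.sqrt(n)
        assert abs(totals.mean() - expected) < 3 * se


class TestSharedLoad:
    def test_disjoint_carriers_share_nothing(self):
        variants = [Variant("v1", "s", 1, 7.0), Variant("v2", "s", 2, 3.0)]
        a = Individual("a", {"v1": 1, "v2": 0})
        b = Individual("b", {"v1": 0, "v2": 2})
        assert shared_load(a, b, variants) == 0.0

    def test_self_shared_load_is_carried_sum(self):
        variants = [Variant("v1", "s", 1, 7.0), Variant("v2", "s", 2, 3.0)]
        a = Individual("a", {"v1": 1, "v2": 2})
        assert shared_load(a, a, variants) == 10.0

    def test_het_and_hom_carrier_overlap(self):
        variants = [Variant("v1", "s", 1, 5.0)]
        a = Individual("a", {"v1": 1})
        b = Individual("b", {"v1": 2})
        assert shared_load(a, b, variants) == 5.0

    def test_matrix_symmetric_with_carried_diagonal(self, tiny_population):
        matrix = shared_load_matrix(tiny_population)
        np.testing.assert_allclose(matrix.values, matrix.values.T)
        for ind_id in tiny_population.individual_ids:
            ind = tiny_population.individual(ind_id)
            own = sum(
                v.impact_score
                for v in tiny_population.variants
                if (ind.dosage(v.variant_id) or 0) >= 1
            )
            assert matrix.loc[ind_id, ind_id] == pytest.approx(own)


class TestCrossLoadsTable:
    def test_round_trip_and_profile_extraction(self, tmp_path, tiny_population):
        results = all_cross_results(tiny_population)
        assert len(results) == 9
        path = tmp_path / "cross_loads.csv"
        write_cross_loads(path, results)
        frame = read_cross_loads(path)
        assert set(frame.columns) == {"cross_id", "scaffold", "realised_load"}
        assert len(frame) == 9 * 2  # 9 crosses x 2 scaffolds
        profile = profile_from_cross_loads(frame, "XxY")
        original = expected_offspring_profile(CrossSpec("X", "Y"), tiny_population)
        np.testing.assert_allclose(profile.scores, original.profile.scores)
        assert profile.scaffolds == original.profile.scaffolds

    def test_unknown_cross_rejected(self, tiny_population):
        frame = cross_loads_frame(all_cross_results(tiny_population))
        with pytest.raises(KeyError):
            profile_from_cross_loads(frame, "AxB")

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"cross_id": ["a"], "load": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_cross_loads(path)
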