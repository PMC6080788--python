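"""Family-weighted counting measures, odds ratios and the null model."""

import math

import numpy as np
import pytest

import perihull as ph
from perihull import stats
from perihull.stats import StatResult, Z95

from conftest import make_residue, mock_model, singleton_cohort


def flagged_model(model_id, flags, pairs=None):
    """Model whose residues carry (is_hydrophobe, is_protrusion) flags."""
    residues = [
        make_residue(
            i + 1,
            aa="LEU" if h else "ALA",
            ca=(float(i), 0, 0),
            is_hydrophobe=h,
            is_protrusion=p,
            is_vertex=p,
            local_density=10 if p else 40,
        )
        for i, (h, p) in enumerate(flags)
    ]
    return mock_model(model_id, residues, pairs=pairs)


H, P = True, False  # readability helpers for flag tuples


class TestMeanFraction:
    def test_single_protein_ratio(self):
        model = flagged_model(
            "m1", [(True, True), (False, True), (True, True), (False, True)]
        )
        # 2 hydrophobes among 4 protrusions
        fam = ph.Family("f", [model])
        assert ph.mean_fraction(fam, stats.hydrophobe, stats.protrusion) == 0.5

    def test_unweighted_mean_over_proteins(self):
        m1 = flagged_model("m1", [(False, True)])  # ratio 0
        m2 = flagged_model("m2", [(True, True)])  # ratio 1
        fam = ph.Family("f", [m1, m2])
        assert ph.mean_fraction(fam, stats.hydrophobe, stats.protrusion) == 0.5

    def test_identity_selection_is_one(self):
        fam = ph.Family("f", [flagged_model("m", [(True, True), (False, False)])])
        assert ph.mean_fraction(fam, stats.everything, stats.everything) == 1.0

    def test_empty_reference_skipped_and_renormalised(self):
        m1 = flagged_model("m1", [(True, True), (True, True)])  # ratio 1
        m2 = flagged_model("m2", [(False, False)])  # no protrusions: skipped
        fam = ph.Family("f", [m1, m2])
        assert ph.mean_fraction(fam, stats.hydrophobe, stats.protrusion) == 1.0

    def test_all_members_empty_raises(self):
        fam = ph.Family("f", [flagged_model("m", [(False, False)])])
        with pytest.raises(ph.UndefinedResultError):
            ph.mean_fraction(fam, stats.hydrophobe, stats.protrusion)


class TestWeightedCounts:
    def test_family_mean_count(self):
        m1 = flagged_model("m1", [(True, True)] * 4)
        m2 = flagged_model("m2", [(True, True)] * 6)
        cohort = ph.Cohort("c", [ph.Family("f", [m1, m2])])
        assert ph.weighted_count(cohort, stats.hydrophobe) == 5.0

    def test_singleton_families_each_weigh_one(self):
        m1 = flagged_model("m1", [(True, True)] * 4)
        m2 = flagged_model("m2", [(True, True)] * 6)
        cohort = singleton_cohort("c", [m1, m2])
        assert ph.weighted_count(cohort, stats.hydrophobe) == 10.0

    def test_empty_selection_counts_zero(self):
        cohort = singleton_cohort("c", [flagged_model("m", [(False, False)])])
        assert ph.weighted_count(cohort, stats.hydrophobe) == 0.0

    def test_protein_count_heaviside(self):
        m1 = flagged_model("m1", [(True, True)])
        m2 = flagged_model("m2", [(True, True)])
        m3 = flagged_model("m3", [(False, False)])
        cohort = ph.Cohort("c", [ph.Family("f", [m1, m2, m3])])
        assert ph.weighted_protein_count(cohort, stats.hydrophobe) == pytest.approx(2 / 3)
        assert ph.weighted_protein_count(cohort, stats.everything) == 1.0
        assert ph.weighted_protein_count(cohort, stats.ss_class("beta")) == 0.0

    def test_duplicating_family_members_leaves_counts_unchanged(self):
        m1 = flagged_model("m1", [(True, True)] * 3)
        m2 = flagged_model("m2", [(True, True)] * 5)
        base = ph.Cohort("c", [ph.Family("f", [m1, m2])])
        doubled = ph.Cohort(
            "c2", [ph.Family("f", [m1, m2, m1, m2])]
        )
        for sel in (stats.hydrophobe, stats.everything):
            assert ph.weighted_count(base, sel) == pytest.approx(
                ph.weighted_count(doubled, sel)
            )
            assert ph.weighted_protein_count(base, sel) == pytest.approx(
                ph.weighted_protein_count(doubled, sel)
            )


class TestWeightedFractions:
    def test_wald_interval_formula(self):
        # one family engineered so N_{s&r}=5, N_r=10
        flags = [(True, True)] * 5 + [(False, True)] * 5
        cohort = singleton_cohort("c", [flagged_model("m", flags)])
        result = ph.weighted_fraction(cohort, stats.hydrophobe, stats.protrusion)
        assert result.estimate == 0.5
        half = Z95 * math.sqrt(0.25 / 10)
        assert result.lower == pytest.approx(0.5 - half, abs=1e-12)
        assert result.upper == pytest.approx(0.5 + half, abs=1e-12)

    def test_superset_selection_gives_one(self):
        flags = [(True, True)] * 4
        cohort = singleton_cohort("c", [flagged_model("m", flags)])
        result = ph.weighted_fraction(cohort, stats.everything, stats.protrusion)
        assert result.estimate == 1.0

    def test_zero_reference_raises(self):
        cohort = singleton_cohort("c", [flagged_model("m", [(True, False)])])
        with pytest.raises(ph.UndefinedResultError):
            ph.weighted_fraction(cohort, stats.hydrophobe, stats.protrusion)

    def test_protein_fraction(self):
        members = [flagged_model(f"m{i}", [(i < 40, i < 40)]) for i in range(80)]
        cohort = singleton_cohort("c", members)
        result = ph.protein_fraction(cohort, stats.hydrophobe)
        assert result.estimate == 0.5
        assert 0.0 <= result.lower <= result.estimate <= result.upper <= 1.0


class TestPairCounts:
    def test_single_protein_example(self):
        # pairs: both-hydrophobe, one-hydrophobe, neither
        flags = [(True, True), (True, True), (False, True), (False, True)]
        model = flagged_model("m", flags, pairs=[(0, 1), (1, 2), (2, 3)])
        cohort = singleton_cohort("c", [model])
        pc = ph.pair_counts(cohort)
        assert pc.n_pair_both == 1.0
        assert pc.n_pair_one == 2.0
        assert pc.f_both_given_one.estimate == 0.5
        assert pc.e_pair_both.estimate == 1.0

    def test_all_hydrophobic_fraction_is_one(self):
        flags = [(True, True)] * 3
        model = flagged_model("m", flags, pairs=[(0, 1), (1, 2)])
        cohort = singleton_cohort("c", [model])
        assert ph.pair_counts(cohort).f_both_given_one.estimate == 1.0

    def test_no_hydrophobes_is_undefined(self):
        flags = [(False, True)] * 3
        model = flagged_model("m", flags, pairs=[(0, 1), (1, 2)])
        cohort = singleton_cohort("c", [model])
        result = ph.pair_counts(cohort).f_both_given_one
        assert result.undefined
        assert math.isnan(result.estimate)


class TestOddsRatio:
    def _stat(self, frac, trials):
        return StatResult(
            estimate=frac,
            lower=0,
            upper=1,
            successes=frac * trials,
            failures=(1 - frac) * trials,
            estimator="F",
        )

    def test_equal_fractions_give_zero(self):
        result = ph.odds_ratio(self._stat(0.3, 50), self._stat(0.3, 80))
        assert result.estimate == pytest.approx(0.0, abs=1e-15)

    def test_direct_arithmetic(self):
        result = ph.odds_ratio(self._stat(0.5, 100), self._stat(0.2, 100))
        assert result.estimate == pytest.approx(math.log(4.0), abs=1e-12)
        se = math.sqrt(1 / 50 + 1 / 50 + 1 / 20 + 1 / 80)
        assert result.upper - result.estimate == pytest.approx(Z95 * se, abs=1e-12)

    def test_antisymmetry_is_exact(self):
        a, b = self._stat(0.37, 61.5), self._stat(0.81, 23.25)
        fwd = ph.odds_ratio(a, b)
        rev = ph.odds_ratio(b, a)
        assert fwd.estimate == -rev.estimate

    def test_degenerate_fraction_flags_infinite(self):
        result = ph.odds_ratio(self._stat(1.0, 10), self._stat(0.2, 10))
        assert result.infinite
        assert math.isinf(result.estimate)

    def test_undefined_input_propagates(self):
        undefined = StatResult(
            float("nan"), float("nan"), float("nan"), 0, 0, "F", undefined=True
        )
        assert ph.odds_ratio(undefined, self._stat(0.5, 10)).undefined


class TestCoInsertionNull:
    def test_all_hydrophobic_null_is_degenerate(self):
        flags = [(True, True)] * 4
        model = flagged_model("m", flags, pairs=[(0, 1), (1, 2), (2, 3)])
        both, one = ph.co_insertion_null(model, n_samples=50, seed=3)
        assert np.all(both == 3) and np.all(one == 3)

    def test_single_hydrophobe_never_pairs(self):
        flags = [(True, True)] + [(False, True)] * 3
        model = flagged_model("m", flags, pairs=[(0, 1), (1, 2), (2, 3)])
        both, one = ph.co_insertion_null(model, n_samples=50, seed=3)
        assert np.all(both == 0)
        assert np.all(one >= 0)

    def test_no_protrusions_raises(self):
        model = flagged_model("m", [(True, False)] * 3, pairs=[])
        with pytest.raises(ph.UndefinedResultError):
            ph.co_insertion_null(model, n_samples=10, seed=0)

    def test_null_preserves_hydrophobe_count_distribution(self):
        # each sample places exactly k hydrophobes, so 'one' counts are
        # bounded by the pair count and 'both' <= 'one'
        flags = [(True, True), (True, True), (False, True), (False, True)]
        model = flagged_model("m", flags, pairs=[(0, 1), (1, 2), (2, 3)])
        both, one = ph.co_insertion_null(model, n_samples=200, seed=1)
        assert np.all(both <= one)
        assert np.all(one <= 3)

    def test_comparison_on_random_labels_is_near_zero(self):
        rng = np.random.default_rng(11)
        spec = ph.FixtureSpec(n_spikes=10, n_families=12, seed=21,
                              hydrophobe_placement=0.5)
        cohort, _ = ph.make_cohort(spec, name="null-test")
        result = ph.co_insertion_comparison(cohort, n_samples=200, seed=4)
        assert result["ln_r"].lower < 0.0 < result["ln_r"].upper


class TestDensityRangeComparison:
    def test_identical_cohorts_give_zero(self):
        spec = ph.FixtureSpec(n_spikes=6, n_families=4, seed=31)
        cohort, _ = ph.make_cohort(spec, name="same")
        ranges = [(0, 6), (6, 12), (12, 22)]
        rows = ph.density_range_comparison(cohort, cohort, ranges)
        for row in rows:
            if not row["ln_r"].undefined:
                assert row["ln_r"].estimate == pytest.approx(0.0, abs=1e-12)

    def test_empty_range_is_flagged(self):
        spec = ph.FixtureSpec(n_spikes=6, n_families=4, seed=31)
        cohort, _ = ph.make_cohort(spec, name="same")
        rows = ph.density_range_comparison(cohort, cohort, [(1000, 2000)])
        assert rows[0]["ln_r"].undefined
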