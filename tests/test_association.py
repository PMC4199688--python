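"""One-way dosage-class ANOVA, direction of effect, tiers, and the
discovery/validation association pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tetrasnp.association import (
    TraitSpecMeta,
    TraitTable,
    associate_all,
    direction_of_effect,
    oneway_dosage_anova,
    significance_tier,
    validation_transform,
)
from tetrasnp.genotyping import DosageMatrix
from tetrasnp.simulate import simulate_dosages, simulate_trait


def anova_oracle(groups):
    """Brute-force sums-of-squares decomposition."""
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    sst = ((all_y - grand) ** 2).sum()
    ssw = sst - ssb
    dfb, dfw = len(groups) - 1, len(all_y) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, stats.f.sf(F, dfb, dfw), ssb / sst


class TestOnewayAnova:
    def test_perfect_separation(self):
        res = oneway_dosage_anova([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.eta2 == 1.0
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait(self):
        res = oneway_dosage_anova([5, 5, 5, 5], [0, 0, 1, 1])
        assert res.eta2 == 0.0 and res.p_value == 1.0

    def test_hand_computed_three_groups(self):
        # groups {1,2,3},{2,3,4},{4,5,6}: SSB=14, SSW=6, F=7, eta2=0.7
        y = [1, 2, 3, 2, 3, 4, 4, 5, 6]
        g = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        res = oneway_dosage_anova(y, g)
        assert res.F == pytest.approx(7.0)
        assert res.eta2 == pytest.approx(0.7)
        assert res.p_value == pytest.approx(stats.f.sf(7.0, 2, 6))

    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.integers(2, 5)
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(k)]
            y = np.concatenate(groups)
            g = np.concatenate([np.full(len(gr), i) for i, gr in enumerate(groups)])
            res = oneway_dosage_anova(y, g, merge_singletons=False)
            F, p, eta2 = anova_oracle(groups)
            assert res.F == pytest.approx(F, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)
            assert res.eta2 == pytest.approx(eta2, rel=1e-10)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=6), rng.normal(size=9), rng.normal(size=5)]
        y = np.concatenate(groups)
        g = np.concatenate([np.full(len(gr), i) for i, gr in enumerate(groups)])
        res = oneway_dosage_anova(y, g)
        F, p = stats.f_oneway(*groups)
        assert res.F == pytest.approx(F)
        assert res.p_value == pytest.approx(p)

    def test_single_class_not_testable(self):
        res = oneway_dosage_anova([1.0, 2.0, 3.0], [1, 1, 1])
        assert not res.testable
        assert np.isnan(res.p_value)

    def test_singleton_class_merged_into_nearest_dosage(self):
        y = [1.0, 2.0, 3.0, 4.0, 10.0]
        g = [0, 0, 1, 1, 2]  # dosage-2 singleton merges into dosage 1
        res = oneway_dosage_anova(y, g)
        assert res.merged_classes == ((2.0, 1.0),)
        assert res.df_between == 1

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    @settings(deadline=None, max_examples=25)
    def test_eta2_invariant_to_affine_trait_transform(self, shift, scale):
        rng = np.random.default_rng(6)
        y = rng.normal(size=20)
        g = rng.integers(0, 3, size=20)
        base = oneway_dosage_anova(y, g)
        moved = oneway_dosage_anova(scale * y + shift, g)
        assert moved.eta2 == pytest.approx(base.eta2, rel=1e-9)
        assert moved.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_p_invariant_to_class_relabeling(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        g = rng.integers(0, 3, size=30)
        relabeled = np.select([g == 0, g == 1, g == 2], [4, 0, 2])
        a = oneway_dosage_anova(y, g, merge_singletons=False)
        b = oneway_dosage_anova(y, relabeled, merge_singletons=False)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_rank_based_option(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=30)
        g = rng.integers(0, 3, size=30)
        res = oneway_dosage_anova(y, g, rank_based=True)
        groups = [y[g == lv] for lv in np.unique(g)]
        stat, p = stats.kruskal(*groups)
        assert res.F == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


class TestDirectionOfEffect:
    def test_monotone_increasing(self):
        y = [1.0, 1.1, 2.0, 2.1, 3.0, 3.1]
        d = [0, 0, 1, 1, 2, 2]
        assert direction_of_effect(y, d) == "up"

    def test_monotone_decreasing(self):
        y = [3.0, 3.1, 2.0, 2.1, 1.0, 1.1]
        d = [0, 0, 1, 1, 2, 2]
        assert direction_of_effect(y, d) == "down"

    def test_sign_alternation_is_inconsistent(self):
        # class means (10, 14, 6) with tight within-class spread
        y = [10.0, 10.1, 14.0, 14.1, 6.0, 6.1]
        d = [0, 0, 1, 1, 2, 2]
        assert direction_of_effect(y, d) == "inconsistent"

    def test_small_wiggle_is_not_inconsistent(self):
        # the dip is far below tau = 0.25 x pooled within-class SD
        y = [10.0, 20.0, 15.2, 25.2, 15.0, 25.0]
        d = [0, 0, 1, 1, 2, 2]
        assert direction_of_effect(y, d) in {"up", "down"}

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            direction_of_effect([1.0, 2.0], [1, 1])


class TestValidationTransform:
    def test_known_values(self):
        out = validation_transform([1.0, 100.0])
        assert out == pytest.approx([0.0, 2.0])

    def test_variance_closed_form(self):
        out = validation_transform([10.0, 100.0, 1000.0])
        assert np.var(out, ddof=1) == pytest.approx(np.var([1.0, 2.0, 3.0], ddof=1))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            validation_transform([1.0, 0.0])


class TestTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [(0.2, "ns"), (0.05, "ns"), (0.049, "*"), (0.01, "*"), (0.009, "**"),
         (0.001, "**"), (0.0005, "***")],
    )
    def test_tier_map(self, p, tier):
        assert significance_tier(p) == tier


class TestAssociateAll:
    def _dataset(self, n, target_r2, seed, p=0.2):
        rng = np.random.default_rng(seed)
        d = simulate_dosages(n, p, rng)
        y = simulate_trait(d, target_r2, 1.0, rng)
        inds = [f"i{j}" for j in range(n)]
        matrix = DosageMatrix(pd.DataFrame({"L-A_100_G": d}, index=inds))
        traits = TraitTable(pd.DataFrame({"TSC": y}, index=inds))
        return matrix, traits

    def test_null_calibration_at_one_percent(self):
        """Under target_r2=0 the p<0.01 rejection rate sits in the 99%
        binomial interval around 1% over 2000 tests."""
        rng = np.random.default_rng(123)
        n_tests = 2000
        hits = 0
        for _ in range(n_tests):
            d = simulate_dosages(208, 0.2, rng)
            if len(np.unique(d)) < 2:
                continue
            y = rng.normal(size=208)
            res = oneway_dosage_anova(y, d)
            hits += res.p_value < 0.01
        lo, hi = stats.binom.ppf([0.005, 0.995], n_tests, 0.01)
        assert lo <= hits <= hi

    def test_power_at_table_scale_effect(self):
        """A marker explaining 20% of trait variance at n=208 is
        essentially always reportable."""
        for seed in range(20):
            matrix, traits = self._dataset(208, 0.20, seed)
            results = associate_all(matrix, traits, mode="discovery")
            assert any(r.reportable for r in results)

    def test_direction_none_iff_ns(self):
        matrix, traits = self._dataset(120, 0.1, 5)
        for r in associate_all(matrix, traits):
            assert (r.direction == "none") == (r.tier == "ns")

    def test_validation_mode_applies_declared_log10(self):
        rng = np.random.default_rng(9)
        n = 40
        d = simulate_dosages(n, 0.3, rng)
        y_log = simulate_trait(d, 0.4, 0.25, rng)
        inds = [f"i{j}" for j in range(n)]
        matrix = DosageMatrix(pd.DataFrame({"L-A_5_G": d}, index=inds))
        traits = TraitTable(
            pd.DataFrame({"T0": 10.0**y_log}, index=inds),
            metadata={"T0": TraitSpecMeta(transform="log10")},
        )
        res_val = associate_all(matrix, traits, mode="validation")[0]
        direct = oneway_dosage_anova(y_log, d)
        assert res_val.p_value == pytest.approx(direct.p_value, rel=1e-9)

    def test_id_mismatch_raises(self):
        matrix, traits = self._dataset(20, 0.0, 1)
        other = TraitTable(traits.values.set_axis([f"x{j}" for j in range(20)]))
        with pytest.raises(ValueError):
            associate_all(matrix, other)

    def test_mfa_filter_modes(self):
        inds = [f"i{j}" for j in range(208)]
        rare = [1] * 5 + [0] * 203  # 5 carriers: validation keeps, discovery drops
        common = [1] * 30 + [0] * 178
        matrix = DosageMatrix(pd.DataFrame({"L-A_1_G": rare, "L-A_2_G": common}, index=inds))
        traits = TraitTable(pd.DataFrame({"t": np.random.default_rng(0).normal(size=208)}, index=inds))
        disc = {r.marker_id for r in associate_all(matrix, traits, mode="discovery")}
        val = {r.marker_id for r in associate_all(matrix, traits, mode="validation")}
        assert disc == {"L-A_2_G"}
        assert val == {"L-A_1_G", "L-A_2_G"}
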