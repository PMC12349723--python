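"""MTT survival, LC-MS/MS substrate classification, DAU accumulation math."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgpscreen import (AccumulationSample, TrialTest, classify_substrate,
                       dau_fold_change, hit_rate, mean_ratio,
                       mtt_resensitization, normalized_ratio,
                       percent_survival, resensitization_call,
                       substrate_ttest)


def _plate(rows):
    return pd.DataFrame(rows, columns=["well_id", "cell_line", "treatment",
                                       "compound_id", "absorbance"])


class TestPercentSurvival:
    def test_well_at_control_mean_is_100(self):
        df = _plate([("w1", "r", "vehicle", None, 0.8),
                     ("w2", "r", "vehicle", None, 1.2),
                     ("w3", "r", "chemo-only", None, 1.0)])
        per_well, _ = percent_survival(df)
        assert per_well.loc[2, "pct_survival"] == pytest.approx(100.0)

    def test_zero_absorbance_is_zero_pct(self):
        df = _plate([("w1", "r", "vehicle", None, 1.0),
                     ("w2", "r", "chemo-only", None, 0.0)])
        per_well, _ = percent_survival(df)
        assert per_well.loc[1, "pct_survival"] == 0.0

    def test_forced_arithmetic(self):
        df = _plate([("w1", "r", "vehicle", None, 0.8),
                     ("w2", "r", "vehicle", None, 1.2),
                     ("w3", "r", "compound+chemo", "c1", 0.5)])
        per_well, _ = percent_survival(df)
        assert per_well.loc[2, "pct_survival"] == pytest.approx(50.0)

    def test_control_group_averages_to_exactly_100(self):
        rng = np.random.default_rng(8)
        df = _plate([(f"w{i}", "r", "vehicle", None, a)
                     for i, a in enumerate(rng.uniform(0.5, 1.5, 24))])
        per_well, _ = percent_survival(df)
        assert per_well["pct_survival"].mean() == pytest.approx(100.0)

    def test_nonpositive_control_fatal(self):
        df = _plate([("w1", "r", "vehicle", None, 0.0),
                     ("w2", "r", "chemo-only", None, 1.0)])
        with pytest.raises(ValueError, match="control"):
            percent_survival(df)


class TestResensitization:
    @pytest.mark.parametrize("chemo,combo,expected_call,expected_dec", [
        (90.0, 55.0, True, 35.0),
        (90.0, 61.0, False, 29.0),
        (90.0, 60.0, True, 30.0),  # "30% or greater" is inclusive
    ])
    def test_rule_and_boundary(self, chemo, combo, expected_call,
                               expected_dec):
        call, dec = resensitization_call(chemo, combo)
        assert call is expected_call
        assert dec == pytest.approx(expected_dec)

    def test_pipeline_from_plate(self):
        rows = [("v1", "r", "vehicle", None, 1.0),
                ("v2", "r", "vehicle", None, 1.0),
                ("p1", "r", "chemo-only", None, 0.9),
                ("p2", "r", "chemo-only", None, 0.9)]
        rows += [(f"h{i}", "r", "compound+chemo", "hit", 0.40)
                 for i in range(3)]
        rows += [(f"m{i}", "r", "compound+chemo", "miss", 0.80)
                 for i in range(3)]
        results = {r.compound_id: r for r in mtt_resensitization(_plate(rows))}
        assert results["hit"].resensitizer
        assert results["hit"].decrease == pytest.approx(50.0)
        assert not results["miss"].resensitizer


def _sample(analyte, is_peak=2000.0, lysate=0.5, **kw):
    base = dict(compound_id="c", condition="minus_TQR", trial=1)
    base.update(kw)
    return AccumulationSample(analyte_peak=analyte, is_peak=is_peak,
                              lysate=lysate, **base)


class TestNormalizedRatio:
    def test_forced_arithmetic(self):
        assert normalized_ratio(_sample(1000.0)) == pytest.approx(1.0)

    def test_zero_analyte(self):
        assert normalized_ratio(_sample(0.0)) == 0.0

    def test_doubling_lysate_halves_ratio(self):
        assert normalized_ratio(_sample(1000.0, lysate=1.0)) == \
            pytest.approx(normalized_ratio(_sample(1000.0, lysate=0.5)) / 2)

    def test_zero_is_peak_fatal_names_sample(self):
        with pytest.raises(ValueError, match="IS peak"):
            normalized_ratio(_sample(1000.0, is_peak=0.0))

    def test_scale_consistency_of_mean(self):
        samples = [_sample(a) for a in (900.0, 1000.0, 1100.0)]
        scaled = [_sample(3 * a) for a in (900.0, 1000.0, 1100.0)]
        m, _ = mean_ratio(samples)
        m3, _ = mean_ratio(scaled)
        assert m3 == pytest.approx(3 * m)


class TestMeanRatio:
    def test_constant_triplicate(self):
        m, sd = mean_ratio([_sample(1000.0)] * 3)
        assert (m, sd) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_forced_arithmetic(self):
        m, sd = mean_ratio([_sample(a, is_peak=1000.0, lysate=1.0)
                            for a in (0.9e3, 1.0e3, 1.1e3)])
        assert m == pytest.approx(1.0)
        assert sd == pytest.approx(0.1)

    def test_permutation_invariance(self):
        vals = [700.0, 1000.0, 1600.0]
        fwd = mean_ratio([_sample(a) for a in vals])
        rev = mean_ratio([_sample(a) for a in reversed(vals)])
        assert fwd == pytest.approx(rev)

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            mean_ratio([])


class TestSubstrateTTest:
    # printed reference rows: (minus mean, sd, plus mean, sd, p to 1 s.f.)
    @pytest.mark.parametrize("m1,s1,m2,s2,printed_p,significant", [
        (0.049, 0.005, 0.146, 0.018, 0.0008, True),   # strong accumulation
        (2.63, 0.52, 3.75, 0.34, 0.04, True),          # borderline
        (0.121, 0.005, 0.163, 0.032, 0.09, False),     # not significant
    ])
    def test_reproduces_printed_panel_p_values(self, m1, s1, m2, s2,
                                               printed_p, significant):
        t, p = substrate_ttest(m1, s1, 3, m2, s2, 3)
        # one significant figure, as printed
        rounded = round(p, -int(math.floor(math.log10(p))))
        assert rounded == pytest.approx(printed_p)
        assert (p < 0.05) is significant

    def test_equal_groups_give_t0_p1(self):
        assert substrate_ttest(1.0, 0.2, 3, 1.0, 0.2, 3) == (0.0, 1.0)

    def test_zero_variance_equal_means(self):
        assert substrate_ttest(1.0, 0.0, 3, 1.0, 0.0, 3) == (0.0, 1.0)

    def test_zero_variance_unequal_means_warns_infinite_t(self):
        with pytest.warns(UserWarning, match="infinite"):
            t, p = substrate_ttest(1.0, 0.0, 3, 2.0, 0.0, 3)
        assert math.isinf(t) and p == 0.0

    def test_agrees_with_independent_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            m1, m2 = rng.uniform(0, 5, 2)
            s1, s2 = rng.uniform(0.05, 1.0, 2)
            t, p = substrate_ttest(m1, s1, 3, m2, s2, 3)
            t_ref, p_ref = stats.ttest_ind_from_stats(m2, s2, 3, m1, s1, 3,
                                                      equal_var=True)
            assert t == pytest.approx(t_ref, rel=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-12)

    def test_agrees_with_permutation_test_on_raw_triplicates(self):
        # sanity oracle: pooled-t p vs exhaustive label permutations on raw
        # replicates (20 arrangements of 3+3 → p resolution 0.1)
        rng = np.random.default_rng(12)
        minus = rng.normal(1.0, 0.1, 3)
        plus = rng.normal(2.0, 0.1, 3)
        t, p = substrate_ttest(minus.mean(), minus.std(ddof=1), 3,
                               plus.mean(), plus.std(ddof=1), 3)
        from itertools import combinations
        pooled = np.concatenate([minus, plus])
        obs = abs(plus.mean() - minus.mean())
        count = 0
        total = 0
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += diff >= obs - 1e-12
            total += 1
        p_perm = count / total
        # perfectly separated groups: both routes call it significant at
        # the permutation test's resolution floor (2/20)
        assert p < 0.05 and p_perm <= 0.1


def _trial(p, up=True, indet=False, trial=1):
    return TrialTest(trial, 1.0, 0.1, 2.0 if up else 0.5, 0.1, 3,
                     0.0, p, p < 0.05, up, indet)


class TestClassifySubstrate:
    def test_any_significant_increase_calls_substrate(self):
        call = classify_substrate("c", [_trial(0.6), _trial(0.01, trial=2)])
        assert call.substrate

    def test_direction_rule_blocks_decreases(self):
        call = classify_substrate("c", [_trial(0.04, up=False)])
        assert not call.substrate

    def test_indeterminate_trials_never_trigger(self):
        call = classify_substrate("c", [_trial(0.001, indet=True)])
        assert not call.substrate
        assert call.indeterminate

    def test_no_trials_fatal(self):
        with pytest.raises(ValueError):
            classify_substrate("c", [])


class TestDauFoldChange:
    def test_identical_means_fold_one(self):
        r = dau_fold_change([1000.0] * 3, [1000.0] * 3)
        assert r.fold_change == pytest.approx(1.0)

    def test_double_mean_fold_two(self):
        r = dau_fold_change([2000.0, 2000.0, 2000.0],
                            [1000.0, 1000.0, 1000.0])
        assert r.fold_change == pytest.approx(2.0)

    def test_cross_implementation_oracle(self):
        rng = np.random.default_rng(16)
        comp = rng.normal(1500.0, 100.0, 9)
        dau = rng.normal(1000.0, 100.0, 9)
        r = dau_fold_change(comp, dau)
        t_ref, p_ref = stats.ttest_ind(comp, dau, equal_var=True)
        assert r.fold_change == pytest.approx(comp.mean() / dau.mean())
        assert r.p_two_sided == pytest.approx(p_ref, rel=1e-10)

    def test_nonpositive_denominator_fatal(self):
        with pytest.raises(ValueError, match="non-positive"):
            dau_fold_change([1000.0] * 3, [0.0] * 3)

    def test_blank_subtraction(self):
        r = dau_fold_change([1100.0] * 3, [600.0] * 3, blank=100.0)
        assert r.fold_change == pytest.approx(2.0)


class TestHitRate:
    def test_screen_scale_reporting(self):
        assert hit_rate(67, 9) == 13.4

    def test_bounds(self):
        with pytest.raises(ValueError):
            hit_rate(0, 0)
        with pytest.raises(ValueError):
            hit_rate(10, 11)
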