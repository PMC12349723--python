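"""ΔG→K_D conversion, DBD/NBD ratios, ranking, and the two-round screen."""

import math

import numpy as np
import pytest

from pgpscreen import (AffinityEstimate, DockingResult, PlantedLandscape,
                       RatioScore, aggregate_ratios, gen_ligand_library,
                       iterate_screen, kd_from_dg, mock_dock,
                       rank_and_select, ratio_score, score_ligands)
from pgpscreen.counterselect import BODY_TEMPERATURE_K, GAS_CONSTANT_KCAL


class TestKdFromDg:
    def test_zero_energy_gives_unit_kd(self):
        assert kd_from_dg(0.0) == 1.0

    def test_minus_eight_kcal(self):
        # exp(-8/0.61597), frozen from an exact-rational high-precision
        # evaluation: 2.2884278553432811528e-6
        assert kd_from_dg(-8.0) == pytest.approx(2.2884278553e-06,
                                                 rel=1e-9)

    def test_monotone_in_dg(self):
        assert kd_from_dg(-9.0) < kd_from_dg(-6.0) < kd_from_dg(0.0)

    def test_inverts_definition_to_machine_precision(self):
        rng = np.random.default_rng(0)
        rt = GAS_CONSTANT_KCAL * BODY_TEMPERATURE_K
        for dg in rng.uniform(-12, 0, size=200):
            assert rt * math.log(kd_from_dg(dg)) == pytest.approx(
                dg, rel=1e-12, abs=1e-12)

    def test_nonfinite_fatal(self):
        with pytest.raises(ValueError):
            kd_from_dg(float("nan"))
        with pytest.raises(ValueError):
            kd_from_dg(float("inf"))


def _est(lid, tid, dg, group=None):
    return AffinityEstimate(lid, tid, dg, pair_group=group)


class TestRatioScore:
    def test_equal_energies_ratio_one(self):
        assert ratio_score(_est("l", "d", -7.0), _est("l", "n", -7.0)) == 1.0

    def test_nbd_preference_value(self):
        # ΔG^DBD−ΔG^NBD = 3 kcal/mol → exp(3/0.61597) ≈ 130.3687617
        r = ratio_score(_est("l", "d", -6.0), _est("l", "n", -9.0))
        assert r == pytest.approx(130.36876170681518, rel=1e-12)

    def test_reciprocal_symmetry(self):
        fwd = ratio_score(_est("l", "d", -6.0), _est("l", "n", -9.0))
        rev = ratio_score(_est("l", "d", -9.0), _est("l", "n", -6.0))
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_shift_invariance_over_random_pairs(self):
        rng = np.random.default_rng(1)
        n = 10_000
        dbd = rng.uniform(-12, -2, n)
        nbd = rng.uniform(-12, -2, n)
        shift = rng.uniform(-5, 5, n)
        for i in range(n):
            a = ratio_score(_est("l", "d", dbd[i]), _est("l", "n", nbd[i]))
            b = ratio_score(_est("l", "d", dbd[i] + shift[i]),
                            _est("l", "n", nbd[i] + shift[i]))
            assert abs(a - b) <= 1e-12 * max(abs(a), abs(b))

    def test_pair_group_mismatch_fatal(self):
        with pytest.raises(ValueError, match="pair_group"):
            ratio_score(_est("l", "d", -6.0, "g1"),
                        _est("l", "n", -9.0, "g2"))

    def test_ligand_mismatch_fatal(self):
        with pytest.raises(ValueError, match="ligand"):
            ratio_score(_est("a", "d", -6.0), _est("b", "n", -9.0))


class TestAggregateRatios:
    def test_single_pair_both_policies(self):
        assert aggregate_ratios({"g": 7.5}, "min") == 7.5
        assert aggregate_ratios({"g": 7.5}, "geometric-mean") == \
            pytest.approx(7.5)

    def test_min_and_geometric_mean(self):
        ratios = {"a": 100.0, "b": 4.0}
        assert aggregate_ratios(ratios, "min") == 4.0
        assert aggregate_ratios(ratios, "geometric-mean") == \
            pytest.approx(20.0)

    def test_missing_pair_zeroes_min_policy(self):
        assert aggregate_ratios({"a": 100.0}, "min", missing_pairs=1) == 0.0
        assert aggregate_ratios({"a": 100.0}, "min", missing_pairs=1,
                                missing="skip") == 100.0

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            aggregate_ratios({}, "min")


class TestRankAndSelect:
    def _scores(self, aggs):
        return [RatioScore(lid, {"g": a}, a)
                for lid, a in aggs.items()]

    def test_top_n_descending(self):
        ranking = rank_and_select(
            self._scores({"a": 5.0, "b": 2.0, "c": 9.0}), n=2)
        assert ranking.ids() == ["c", "a"]

    def test_tie_broken_by_ligand_id(self):
        ranking = rank_and_select(self._scores({"zz": 3.0, "aa": 3.0}), n=2)
        assert ranking.ids() == ["aa", "zz"]

    def test_permutation_invariance(self):
        scores = self._scores({f"l{i}": float((i * 7) % 13)
                               for i in range(13)})
        fwd = rank_and_select(scores, n=5).ids()
        rev = rank_and_select(scores[::-1], n=5).ids()
        assert fwd == rev

    def test_oversized_n_warns_returns_all(self):
        with pytest.warns(UserWarning):
            ranking = rank_and_select(self._scores({"a": 1.0}), n=5)
        assert ranking.ids() == ["a"]


class TestScoreLigands:
    def test_planted_preferrers_beat_background(self, manifest_small):
        lib, _ = gen_ligand_library(60, 12, seed=6)
        planted = frozenset(lib.ids()[:5])
        land = PlantedLandscape(planted_ids=planted,
                                planted_offset_nbd=-3.0)
        scores = score_ligands(mock_dock(lib, manifest_small, land),
                               manifest_small, policy="min")
        planted_aggs = [s.aggregate for s in scores
                        if s.ligand_id in planted]
        background = [s.aggregate for s in scores
                      if s.ligand_id not in planted]
        assert min(planted_aggs) > max(background)

    def test_missing_domain_zeroes_ligand_under_min(self, manifest_small):
        nbd_only = [DockingResult("l0", "open_nbd_1", (-9.0,))]
        (score,) = score_ligands(nbd_only, manifest_small, policy="min")
        assert score.aggregate == 0.0
        assert score.missing_pairs > 0

    def test_multiple_nbd_boxes_use_tightest(self, manifest_small):
        results = [DockingResult("l0", "open_dbd", (-6.0,)),
                   DockingResult("l0", "open_nbd_1", (-7.0,)),
                   DockingResult("l0", "open_nbd_2", (-9.0,))]
        only_open = [t for t in manifest_small if t.pair_group == "open"]
        (score,) = score_ligands(results, only_open)
        expected = math.exp(3.0 / (GAS_CONSTANT_KCAL * BODY_TEMPERATURE_K))
        assert score.per_pair["open"] == pytest.approx(expected, rel=1e-12)


class TestIterateScreen:
    @pytest.fixture
    def planted_setup(self):
        lib, labels = gen_ligand_library(200, 20,
                                         within_cluster_similarity=0.9,
                                         seed=42)
        firsts = {}
        for rec, lab in zip(lib.records, labels):
            firsts.setdefault(lab, rec.ligand_id)
        planted = frozenset(firsts[c] for c in range(6))
        return lib, planted

    def test_noiseless_planted_rank_first(self, planted_setup,
                                          manifest_small):
        lib, planted = planted_setup
        land = PlantedLandscape(planted_ids=planted,
                                planted_offset_nbd=-3.0, noise_sd=0.0)
        out = iterate_screen(lib, manifest_small,
                             lambda l, t: mock_dock(l, t, land),
                             cutoff=0.95, n_top=50)
        ids = out.merged.ids()
        survived = planted & set(ids)
        # all surviving planted ligands precede every background ligand
        first_background = next(i for i, x in enumerate(ids)
                                if x not in planted)
        assert first_background == len(survived) == len(planted)

    def test_degenerate_band_skips_round_two(self, manifest_small):
        # singleton clusters: no pool ligand is exactly similar to another,
        # so a [1.0, 1.0] band can match nothing but the queries themselves
        lib, _ = gen_ligand_library(30, 30, seed=42)
        planted = frozenset(lib.ids()[:6])
        land = PlantedLandscape(planted_ids=planted)
        out = iterate_screen(lib, manifest_small,
                             lambda l, t: mock_dock(l, t, land),
                             cutoff=0.95, band=(1.0, 1.0), n_top=50)
        assert out.round2 is None
        assert out.provenance["expansion_size"] == 0
        assert out.merged.ids() == out.round1.ids()[:len(out.merged.ids())]

    def test_noisy_recovery_at_fixed_seed(self, planted_setup,
                                          manifest_small):
        lib, planted = planted_setup
        land = PlantedLandscape(planted_ids=planted,
                                planted_offset_nbd=-3.0, noise_sd=0.5,
                                seed=7)
        out = iterate_screen(lib, manifest_small,
                             lambda l, t: mock_dock(l, t, land),
                             cutoff=0.95, n_top=50)
        top = set(out.merged.ids()[:len(planted)])
        assert len(top & planted) >= len(planted) - 1

    def test_recovery_improves_as_noise_shrinks(self, planted_setup,
                                                manifest_small):
        lib, planted = planted_setup
        recoveries = []
        for noise in (2.0, 0.5, 0.0):
            land = PlantedLandscape(planted_ids=planted,
                                    planted_offset_nbd=-3.0,
                                    noise_sd=noise, seed=3)
            out = iterate_screen(lib, manifest_small,
                                 lambda l, t: mock_dock(l, t, land),
                                 cutoff=0.95, n_top=50)
            top = set(out.merged.ids()[:len(planted)])
            recoveries.append(len(top & planted))
        assert recoveries == sorted(recoveries)
        assert recoveries[-1] == len(planted)
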