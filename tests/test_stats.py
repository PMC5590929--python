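"""Enrichment statistics, proportion tests and positional profiles."""

import math

import numpy as np
import pytest

from structmap.stats import (AMINO_ACIDS, ContingencyTable2x2, DisorderTrack,
                             classify_disordered, disorder_odds_profile,
                             fisher_exact_or, proportion_ci,
                             relative_entropy_profile, score_comparison,
                             two_proportion_ztest)
from structmap.synthetic import generate_disorder_tracks

UNIFORM = np.full(20, 0.05)


def tracks_of(d):
    t = {k: DisorderTrack(k, d["method"], v, d["threshold"])
         for k, v in d["target_tracks"].items()}
    b = {k: DisorderTrack(k, d["method"], v, d["threshold"])
         for k, v in d["background_tracks"].items()}
    return t, b


class TestFisher:
    def test_rem465_published_counts(self):
        # 26/143 modified vs 553/4811 unmodified in missing regions
        odds, p = fisher_exact_or(ContingencyTable2x2(26, 117, 553, 4258))
        assert round(odds, 1) == 1.7
        assert round(p, 2) == 0.02

    def test_symmetric_table(self):
        odds, p = fisher_exact_or(ContingencyTable2x2(5, 5, 5, 5))
        assert odds == 1.0 and p == 1.0

    def test_row_swap_inverts_odds(self):
        t = ContingencyTable2x2(20, 10, 5, 40)
        odds, p = fisher_exact_or(t)
        swapped, p2 = fisher_exact_or(ContingencyTable2x2(5, 40, 20, 10))
        assert swapped == pytest.approx(1.0 / odds)
        assert p2 == pytest.approx(p)

    def test_column_swap_inverts_odds(self):
        odds, _ = fisher_exact_or(ContingencyTable2x2(20, 10, 5, 40))
        swapped, _ = fisher_exact_or(ContingencyTable2x2(10, 20, 40, 5))
        assert swapped == pytest.approx(1.0 / odds)

    def test_zero_cell_haldane(self):
        with pytest.warns(UserWarning, match="Haldane"):
            odds, _ = fisher_exact_or(ContingencyTable2x2(0, 10, 5, 40))
        assert math.isfinite(odds) and odds > 0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 5, 40)


class TestTwoProportionZ:
    def test_published_row_e(self):
        _, p = two_proportion_ztest(66, 1377, 4495, 100329)
        assert round(p, 1) == 0.6

    def test_published_rows_c_and_h(self):
        _, p_c = two_proportion_ztest(1205, 1377, 83150, 100329)
        _, p_h = two_proportion_ztest(106, 1377, 12684, 100329)
        assert p_c < 0.01 and p_h < 0.01

    def test_identical_proportions(self):
        z, p = two_proportion_ztest(10, 100, 30, 300)
        assert z == 0.0 and p == 1.0

    def test_degenerate_pooled_proportion(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = two_proportion_ztest(0, 50, 0, 80)
        assert p == 1.0


class TestProportionCi:
    def test_published_intervals(self):
        assert [round(v, 2) for v in proportion_ci(78, 143)] == [0.46, 0.63]
        assert [round(v, 2) for v in proportion_ci(36, 143)] == [0.18, 0.32]

    def test_zero_successes_clipped(self):
        low, high = proportion_ci(0, 50)
        assert low == 0.0 and high == 0.0

    def test_width_shrinks_with_root_n(self):
        low1, high1 = proportion_ci(30, 100)
        low4, high4 = proportion_ci(120, 400)
        assert (high4 - low4) == pytest.approx((high1 - low1) / 2, rel=1e-9)


class TestScoreComparison:
    def test_identical_groups(self, rng):
        x = rng.normal(size=50)
        res = score_comparison(x, x, test="t")
        assert res["p"] == pytest.approx(1.0)
        assert res["statistic"] == pytest.approx(0.0)

    def test_shifted_normals_detected(self, rng):
        x = rng.normal(0.0, 1.0, 200)
        y = rng.normal(1.0, 1.0, 200)
        assert score_comparison(x, y, test="t")["p"] < 0.01
        assert score_comparison(x, y, test="kruskal_wallis")["p"] < 0.01

    def test_permuted_group_t_zero(self, rng):
        x = rng.normal(size=100)
        res = score_comparison(x, rng.permutation(x), test="t")
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_groups_kw_error(self):
        with pytest.raises(ValueError):
            score_comparison([1.0, 1.0], [1.0, 1.0], test="kruskal_wallis")


class TestRelativeEntropy:
    def test_background_frequencies_give_zero(self):
        # every column contains each amino acid once -> p == q == uniform
        flanks = ["".join(AMINO_ACIDS[(i + j) % 20] for j in range(7))
                  for i in range(20)]
        prof = relative_entropy_profile(flanks, UNIFORM, reps=30, seed=0)
        assert np.abs(prof.values).max() <= 1e-9

    def test_st_central_column_is_maximum(self, rng):
        flanks = []
        for _ in range(400):
            left = "".join(rng.choice(list(AMINO_ACIDS), 3))
            right = "".join(rng.choice(list(AMINO_ACIDS), 3))
            flanks.append(left + str(rng.choice(["S", "T"])) + right)
        prof = relative_entropy_profile(flanks, UNIFORM, reps=30, seed=1)
        assert prof.offsets[np.argmax(prof.values)] == 0

    def test_single_letter_column_hand_value(self):
        # n sites all 'A' at each column, uniform background, pseudocount 0.5
        n = 50
        flanks = ["AAAAAAA"] * n
        p_a = (n + 0.5) / (n + 10.0)
        p_other = 0.5 / (n + 10.0)
        expected = p_a * math.log2(p_a / 0.05) \
            + 19 * p_other * math.log2(p_other / 0.05)
        prof = relative_entropy_profile(flanks, UNIFORM, reps=10, seed=0)
        assert prof.values == pytest.approx(np.full(7, expected))

    def test_gap_padded_positions_excluded(self):
        prof = relative_entropy_profile(["---S---"] * 30, UNIFORM, reps=10,
                                        seed=0)
        assert np.isnan(prof.values[[0, 1, 2, 4, 5, 6]]).all()
        assert prof.values[3] > 1.0

    def test_non_negative(self, rng):
        flanks = ["".join(rng.choice(list(AMINO_ACIDS), 7))
                  for _ in range(100)]
        prof = relative_entropy_profile(flanks, UNIFORM, reps=10, seed=2)
        assert np.nanmin(prof.values) >= -1e-12

    def test_band_contains_estimate(self, rng):
        flanks = ["".join(rng.choice(list(AMINO_ACIDS), 7))
                  for _ in range(60)]
        prof = relative_entropy_profile(flanks, UNIFORM, reps=50, seed=3)
        assert np.all(prof.ci_low <= prof.values + 1e-12)
        assert np.all(prof.values <= prof.ci_high + 1e-12)


class TestDisorderProfiles:
    def test_identical_tracks_give_zero(self, rng):
        scores = {f"P{i}": rng.random(101) for i in range(40)}
        tr = {k: DisorderTrack(k, "JRonn", v) for k, v in scores.items()}
        sites = [(k, 51) for k in scores]
        prof = disorder_odds_profile(tr, sites, tr, sites, window=20)
        assert np.allclose(prof.values, 0.0)

    def test_planted_enrichment_recovered(self):
        # the 95% band at offset 0 covers the planted log-odds in most
        # seeded runs (a single run misses ~5% of the time by design)
        covered = 0
        far_covered = 0
        n_runs = 20
        for seed in range(n_runs):
            d = generate_disorder_tracks(300, 600, seed=seed)
            t, b = tracks_of(d)
            prof = disorder_odds_profile(t, d["target_sites"], b,
                                         d["background_sites"], window=25)
            _, low, high = prof.at(0)
            covered += low <= d["planted_log10_or"] <= high
            # enrichment is localised: offsets outside the planted window
            # are consistent with zero
            _, far_low, far_high = prof.at(25)
            far_covered += far_low <= 0.0 <= far_high
        assert covered >= int(0.8 * n_runs)
        assert far_covered >= int(0.8 * n_runs)

    def test_threshold_above_all_scores_finite(self, rng):
        tr = {"P1": DisorderTrack("P1", "JRonn", rng.random(61) * 0.1,
                                  threshold=0.9)}
        sites = [("P1", 31)]
        prof = disorder_odds_profile(tr, sites, tr, sites, window=5)
        assert np.isfinite(prof.values).all()

    def test_mixed_methods_rejected(self, rng):
        a = {"P1": DisorderTrack("P1", "JRonn", rng.random(10))}
        b = {"P2": DisorderTrack("P2", "IUPred-Long", rng.random(10))}
        with pytest.raises(ValueError, match="mixed"):
            disorder_odds_profile(a, [("P1", 5)], b, [("P2", 5)], window=2)


class TestClassifyDisordered:
    def test_boundary_inclusive(self):
        track = DisorderTrack("P1", "JRonn", [0.5, 0.49])
        assert classify_disordered(track, 1) is True
        assert classify_disordered(track, 2) is False

    def test_hotloops_threshold(self):
        track = DisorderTrack("P1", "DisEMBL-HOTLOOPS", [0.12])
        assert classify_disordered(track, 1) is False

    def test_nan_score_is_error(self):
        track = DisorderTrack("P1", "JRonn", [float("nan")])
        with pytest.raises(ValueError):
            classify_disordered(track, 1)
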