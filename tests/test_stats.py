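"""Sectioning, aggregation, distraction ratios, and the statistical battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gazeload as gz
from gazeload.scene import POSTER_LABELS
from gazeload.stats import (
    DegenerateDataError,
    adjacent_pair_battery,
    benjamini_hochberg,
    cohens_d,
    distraction_ratio,
    metric_battery,
    rank_sum_test,
    rotation_angles_deg,
    section_slices,
    spearman_rho,
)


class TestSectioning:
    def test_four_half_open_windows(self):
        t = np.arange(0.0, 45.0, 1.0 / 90.0)
        masks = section_slices(t)
        assert len(masks) == 4
        # a sample at exactly 10 s belongs to section 2, not 1
        i10 = np.argmin(np.abs(t - 10.0))
        assert t[i10] == pytest.approx(10.0)
        assert not masks[0][i10]
        assert masks[1][i10]
        for a, b in itertools.combinations(masks, 2):
            assert not (a & b).any()

    def test_short_trial_error_names_shortfall(self):
        t = np.arange(0.0, 39.9, 1.0 / 90.0)
        with pytest.raises(ValueError, match="short"):
            section_slices(t)

    def test_invariant_to_rechunking(self):
        """Sectioning depends only on timestamps, not array chunking."""
        t = np.arange(0.0, 45.0, 1.0 / 90.0)
        whole = [m.sum() for m in section_slices(t)]
        again = [m.sum() for m in section_slices(t.copy())]
        assert whole == again


class TestRotationAngles:
    def test_static_vectors_have_zero_variance(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        assert np.allclose(rotation_angles_deg(v), 0.0)

    def test_alternating_angles_hand_computed(self):
        """Steps of 0.1 and 0.3 degrees give the variance of {0.1, 0.3}."""
        angles = []
        a = 0.0
        for step in itertools.islice(itertools.cycle([0.1, 0.3]), 40):
            a += step
            angles.append(a)
        vs = np.array(
            [[np.sin(np.radians(x)), 0.0, np.cos(np.radians(x))] for x in [0.0] + angles]
        )
        steps = rotation_angles_deg(vs)
        assert np.allclose(np.sort(np.unique(np.round(steps, 9))), [0.1, 0.3])
        assert np.var(steps, ddof=1) == pytest.approx(np.var([0.1, 0.3] * 20, ddof=1), rel=1e-6)


class TestDistractionRatio:
    def test_single_poster_takes_all(self):
        labels = np.array(["poster_left"] * 30 + ["target_sphere"] * 100, dtype=object)
        out = distraction_ratio(labels, POSTER_LABELS)
        assert out == {"poster_left": 1.0, "poster_right": 0.0, "poster_front": 0.0}

    def test_share_arithmetic(self):
        labels = np.array(
            ["poster_left"] * 30 + ["poster_right"] * 10 + ["poster_front"] * 10,
            dtype=object,
        )
        out = distraction_ratio(labels, POSTER_LABELS)
        assert out == {"poster_left": 0.6, "poster_right": 0.2, "poster_front": 0.2}
        assert sum(out.values()) == pytest.approx(1.0)

    def test_no_poster_contact_is_undefined(self):
        labels = np.array(["target_sphere"] * 50, dtype=object)
        assert distraction_ratio(labels, POSTER_LABELS) is None

    def test_unknown_poster_label_is_an_error(self):
        labels = np.array(["poster_bogus"], dtype=object)
        with pytest.raises(ValueError):
            distraction_ratio(labels, POSTER_LABELS)


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    def test_zero_pooled_sd_with_unequal_means(self):
        assert cohens_d(5.0, 0.0, 10, 6.0, 0.0, 10) == np.inf

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            cohens_d(5.0, 1.0, 1, 6.0, 1.0, 10)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        """{0.01, 0.02, 0.03} all adjust to 0.03 under the step-up rule."""
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(benjamini_hochberg([0.04] * 5), 0.04)

    def test_empty_family_is_an_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_explicit_step_up_oracle(self, ps):
        """BH equals the textbook step-up computation with running minima."""
        adj = benjamini_hochberg(ps)
        m = len(ps)
        order = np.argsort(ps)
        oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            oracle[i] = running
        assert np.allclose(adj, oracle, atol=1e-12)


class TestRankSum:
    def test_exact_statistic_matches_enumeration(self):
        """For tiny groups the p-value equals exhaustive enumeration over all
        rank assignments."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        u, p = rank_sum_test(x, y)
        # enumerate all C(6,3)=20 assignments of the pooled ranks
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        obs_u = u
        stats = []
        for combo in itertools.combinations(range(6), 3):
            r = ranks[list(combo)].sum()
            u1 = r - 3 * 4 / 2
            stats.append(min(u1, 9 - u1))
        obs = min(obs_u, 9 - obs_u)
        p_oracle = np.mean([s <= obs for s in stats])
        assert p == pytest.approx(p_oracle, abs=1e-12)


class TestSpearman:
    def test_perfectly_decreasing_is_minus_one(self):
        rho, _ = spearman_rho(np.arange(10.0), np.arange(10.0)[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_fixture(self):
        """Five pairs against the direct rank-formula oracle."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 3.0, 2.5, 4.0])
        rho, _ = spearman_rho(x, y)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_independent_shuffle_is_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        rho, _ = spearman_rho(x, y)
        assert abs(rho) < 0.06

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho(np.ones(5), np.arange(5.0))


class TestMetricBattery:
    def test_identical_groups_stop_at_omnibus(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=44)
        groups = {c: base.copy() for c in gz.CONDITIONS}
        report = metric_battery(groups, "pupil_mean")
        assert report.omnibus_p > 0.05
        assert report.pairwise == []

    def test_strong_shift_reaches_pairwise_stage(self):
        rng = np.random.default_rng(9)
        groups = {
            "JP-Familiar": rng.normal(0.0, 1.0, 44),
            "JP-Unfamiliar": rng.normal(0.1, 1.0, 44),
            "EN-Familiar": rng.normal(2.0, 1.0, 44),
            "EN-Unfamiliar": rng.normal(0.2, 1.0, 44),
        }
        report = metric_battery(groups, "pupil_mean")
        assert report.omnibus_p < 0.05
        assert len(report.pairwise) == 6
        adj = [pw.p_adjusted for pw in report.pairwise]
        assert all(0 <= q <= 1 for q in adj)
        enf = [pw for pw in report.pairwise if "EN-Familiar" in pw.pair]
        assert all(pw.p_adjusted < 0.05 for pw in enf)
        assert all(pw.cohens_d > 1.0 for pw in enf)

    def test_constant_everything_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            metric_battery({c: np.ones(10) for c in gz.CONDITIONS}, "x")

    def test_pupil_shift_power_on_simulated_aggregates(self, default_config):
        """With the default effect size, the omnibus flags pupil_mean in the
        vast majority of simulated cohorts (aggregate-level check)."""
        cfg = default_config
        rng = np.random.default_rng(12)
        hits = 0
        n_rep = 40
        sd = 0.15  # section-level spread consistent with the generator
        for _ in range(n_rep):
            groups = {
                c: cfg.expected_section_pupil_shift(c) + rng.normal(0, sd, 44)
                for c in gz.CONDITIONS
            }
            hits += metric_battery(groups, "pupil_mean").omnibus_p < 0.05
        assert hits >= 0.9 * n_rep


class TestAdjacentPairBattery:
    def test_identical_paired_vectors_are_null(self):
        x = np.arange(30.0)
        res = adjacent_pair_battery([("a", "b", x, x.copy())])
        assert res[0].p_raw == pytest.approx(1.0)
        assert res[0].cohens_d == 0.0

    def test_normal_shift_takes_t_branch(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 1.0, 30)
        b = a + rng.normal(0.8, 0.3, 30)
        res = adjacent_pair_battery([("a", "b", a, b)])
        assert res[0].test == "t"
        d_expected = abs(np.mean(a) - np.mean(b)) / np.sqrt(
            (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        )
        assert res[0].cohens_d == pytest.approx(d_expected, rel=1e-9)
        assert res[0].levene_p is not None

    def test_skewed_data_takes_wilcoxon_branch(self):
        rng = np.random.default_rng(11)
        a = rng.exponential(1.0, 30) ** 2
        b = a + rng.exponential(0.5, 30)
        res = adjacent_pair_battery([("a", "b", a, b)])
        assert res[0].test == "wilcoxon"

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            adjacent_pair_battery([("a", "b", np.zeros(5), np.zeros(6))])

    def test_bh_family_spans_all_pairs(self):
        rng = np.random.default_rng(13)
        pairs = []
        for i in range(3):
            a = rng.normal(0, 1, 30)
            pairs.append((f"c{i}", f"c{i+1}", a, a + rng.normal(0.5, 1, 30)))
        res = adjacent_pair_battery(pairs)
        raw = [r.p_raw for r in res]
        assert np.allclose([r.p_adjusted for r in res], benjamini_hochberg(raw))
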