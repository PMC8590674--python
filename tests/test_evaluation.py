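"""Clinical-agreement statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import ripsleep as rs
from ripsleep.types import STAGES


def brute_force_kappa(ref_labels, pred_labels):
    """Two-rater kappa computed directly from the label lists."""
    n = len(ref_labels)
    p_o = np.mean([r == p for r, p in zip(ref_labels, pred_labels)])
    p_e = sum(
        (np.mean([r == s for r in ref_labels]))
        * (np.mean([p == s for p in pred_labels]))
        for s in STAGES
    )
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        hyp = np.repeat(STAGES, 30)
        cm = rs.confusion_matrix(hyp, hyp)
        assert np.array_equal(cm.counts, np.diag([30, 30, 30]))

    def test_total_disagreement(self):
        cm = rs.confusion_matrix(["WAKE"] * 10, ["REM"] * 10)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 10
        assert np.array_equal(cm.counts, expected)

    def test_matches_per_epoch_tally(self, rng):
        ref = rng.choice(STAGES, size=20)
        pred = rng.choice(STAGES, size=20)
        cm = rs.confusion_matrix(ref, pred)
        for i, r in enumerate(STAGES):
            for j, p in enumerate(STAGES):
                assert cm.counts[i, j] == sum(
                    1 for a, b in zip(ref, pred) if a == r and b == p
                )

    def test_length_mismatch_reports_both_lengths(self):
        with pytest.raises(ValueError, match="3.*5|5.*3"):
            rs.confusion_matrix(["WAKE"] * 3, ["WAKE"] * 5)


class TestKappa:
    def test_perfect(self):
        assert rs.cohens_kappa(rs.ConfusionMatrix3(np.diag([100, 100, 100]))) == 1.0

    def test_chance_level(self):
        cm = rs.ConfusionMatrix3(np.full((3, 3), 10))
        assert rs.cohens_kappa(cm) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        cm = rs.ConfusionMatrix3(np.array([[40, 5, 5], [5, 20, 5], [5, 5, 10]]))
        # p_o = 70/100; p_e = (50*50 + 30*30 + 20*20)/100^2 = 0.38
        expected = (0.70 - 0.38) / (1 - 0.38)
        assert rs.cohens_kappa(cm) == pytest.approx(expected)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            rs.cohens_kappa(rs.ConfusionMatrix3(np.zeros((3, 3), dtype=int)))

    def test_matches_expanded_label_oracle_randomized(self, rng):
        """kappa on the matrix equals the two-rater formula on expanded
        label lists, and sklearn's independent implementation, for 100
        random small instances."""
        from sklearn.metrics import cohen_kappa_score

        for _ in range(100):
            n = int(rng.integers(2, 50))
            ref = rng.choice(STAGES, size=n)
            pred = rng.choice(STAGES, size=n)
            cm = rs.confusion_matrix(ref, pred)
            ours = rs.cohens_kappa(cm)
            assert ours == pytest.approx(brute_force_kappa(ref, pred))
            if len(set(ref)) > 1 or len(set(pred)) > 1:
                assert ours == pytest.approx(
                    cohen_kappa_score(ref, pred, labels=list(STAGES))
                )


class TestStageSensitivitySpecificity:
    def test_perfect_diagonal(self):
        cm = rs.ConfusionMatrix3(np.diag([10, 20, 30]))
        for s in STAGES:
            assert rs.stage_sensitivity_specificity(cm, s) == (1.0, 1.0)

    def test_hand_collapsed_example(self):
        cm = rs.ConfusionMatrix3(np.array([[40, 5, 5], [5, 20, 5], [5, 5, 10]]))
        sens, spec = rs.stage_sensitivity_specificity(cm, "WAKE")
        assert sens == pytest.approx(40 / 50)
        assert spec == pytest.approx(40 / 50)

    def test_empty_reference_row_errors(self):
        cm = rs.ConfusionMatrix3(np.array([[5, 0, 0], [0, 0, 0], [0, 0, 5]]))
        with pytest.raises(ValueError, match="REM"):
            rs.stage_sensitivity_specificity(cm, "REM")

    def test_matches_explicit_2x2_collapse_randomized(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 20, size=(3, 3))
            cm = rs.ConfusionMatrix3(counts)
            for i, s in enumerate(STAGES):
                if counts[i].sum() == 0:
                    continue
                rest = [j for j in range(3) if j != i]
                tp = counts[i, i]
                fn = counts[i, rest].sum()
                fp = counts[rest, i].sum()
                tn = counts[np.ix_(rest, rest)].sum()
                sens, spec = rs.stage_sensitivity_specificity(cm, s)
                assert sens == pytest.approx(tp / (tp + fn))
                assert spec == pytest.approx(tn / (tn + fp))


class TestSleepMetrics:
    def test_all_wake(self):
        m = rs.sleep_metrics(["WAKE"] * 20, 0, 10.0)
        assert m.tst == 0 and m.se == 0 and m.ahi is None

    def test_hand_arithmetic(self):
        hyp = ["NREM"] * 240 + ["WAKE"] * 240
        m = rs.sleep_metrics(hyp, 20, 240.0)
        assert m.tst == 120.0
        assert m.se == pytest.approx(50.0)
        assert m.ahi == pytest.approx(10.0)

    def test_all_sleep_no_events(self):
        m = rs.sleep_metrics(["REM"] * 60, 0, 30.0)
        assert m.ahi == 0.0

    def test_undefined_ahi_with_events(self):
        m = rs.sleep_metrics(["WAKE"] * 10, 7, 5.0)
        assert m.ahi is None  # undefined, not zero

    def test_tst_wake_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            hyp = rng.choice(STAGES, size=n)
            m = rs.sleep_metrics(hyp, 0, n * 0.5)
            wake_min = 0.5 * np.sum(hyp == "WAKE")
            assert m.tst + wake_min == pytest.approx(n * 0.5)


class TestSeverityGroup:
    @pytest.mark.parametrize(
        "ahi,group",
        [(0, 1), (4.99, 1), (5, 2), (10, 2), (14.99, 2), (15, 3),
         (29.99, 3), (30, 4), (84.3, 4)],
    )
    def test_bin_map(self, ahi, group):
        assert rs.severity_group(ahi) == group

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            rs.severity_group(-1)

    def test_monotone_in_ahi(self):
        ahis = np.linspace(0, 60, 200)
        groups = [rs.severity_group(a) for a in ahis]
        assert all(b >= a for a, b in zip(groups, groups[1:]))


class TestGroupAccuracy:
    def test_identical_vectors_perfect(self):
        ahis = [2, 8, 20, 40, 3, 12]
        acc = rs.group_accuracy(ahis, ahis)
        for g in (1, 2, 3, 4):
            if acc[g]["n"]:
                assert acc[g]["sensitivity"] == 1.0
            assert acc[g]["specificity"] == 1.0

    def test_hand_tally(self):
        # ref groups (1,2,3,4), est groups (1,2,3,3)
        acc = rs.group_accuracy([2, 10, 20, 35], [2, 10, 20, 20])
        assert acc[4]["sensitivity"] == 0.0
        assert acc[3]["specificity"] == pytest.approx(2 / 3)
        assert acc[3]["n"] == 1

    def test_single_subject(self):
        acc = rs.group_accuracy([20.0], [3.0])
        assert acc[3]["n"] == 1 and acc[3]["sensitivity"] == 0.0
        assert acc[1]["n"] == 0 and acc[1]["sensitivity"] is None

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rs.group_accuracy([], [])


class TestAgreementStats:
    def test_identical_vectors(self):
        out = rs.agreement_stats([1, 2, 3, 4], [1, 2, 3, 4])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["bias"] == 0.0
        assert out["loa"] == (0.0, 0.0)

    def test_constant_offset(self):
        out = rs.agreement_stats([100.0, 200.0, 300.0], [114.0, 214.0, 314.0])
        assert out["bias"] == pytest.approx(14.0)
        assert out["loa"][0] == pytest.approx(14.0)
        assert out["loa"][1] == pytest.approx(14.0)

    def test_hand_computed_example(self):
        ref = np.array([1.0, 2, 3, 4])
        est = np.array([2.0, 2, 4, 5])
        out = rs.agreement_stats(ref, est)
        assert out["bias"] == pytest.approx(np.mean(est - ref))
        # Pearson by the explicit covariance formula
        r = np.sum((ref - ref.mean()) * (est - est.mean())) / (
            np.sqrt(np.sum((ref - ref.mean()) ** 2))
            * np.sqrt(np.sum((est - est.mean()) ** 2))
        )
        assert out["pearson_r"] == pytest.approx(r)

    def test_zero_variance_reports_undefined(self):
        out = rs.agreement_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert out["pearson_r"] is None

    def test_bias_antisymmetry(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert rs.agreement_stats(a, b)["bias"] == pytest.approx(
            -rs.agreement_stats(b, a)["bias"]
        )

    def test_randomized_against_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a = rng.normal(size=n)
            b = a * rng.normal() + rng.normal(size=n)
            out = rs.agreement_stats(a, b)
            assert out["pearson_r"] == pytest.approx(stats.pearsonr(a, b).statistic)
            d = b - a
            assert out["bias"] == pytest.approx(d.mean())
            assert out["loa"][1] - out["bias"] == pytest.approx(
                1.96 * d.std(ddof=1)
            )


class TestSleepOnset:
    def test_identical_hypnograms(self):
        hyp = ["WAKE"] * 15 + ["NREM"] * 30
        out = rs.sleep_onset_agreement(hyp, hyp)
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 1.0
        assert out["f1"] == 1.0

    def test_window_truncated_at_record_start(self):
        ref = ["WAKE"] * 5 + ["NREM"] * 95
        out = rs.sleep_onset_agreement(ref, ref)
        assert out["window"] == (0, 16)
        assert out["n_compared"] == 16

    def test_hand_tally_shifted_onset(self):
        # within the 21-epoch window: reference 10 wake then 11 sleep,
        # prediction 11 wake then 10 sleep
        ref = ["WAKE"] * 10 + ["NREM"] * 30
        pred = ["WAKE"] * 11 + ["NREM"] * 29
        out = rs.sleep_onset_agreement(ref, pred)
        assert (out["tp"], out["fn"], out["fp"], out["tn"]) == (10, 1, 0, 10)
        assert out["sensitivity"] == pytest.approx(10 / 11)
        assert out["specificity"] == 1.0
        assert out["f1"] == pytest.approx(20 / 21)

    def test_all_wake_reference_errors(self):
        with pytest.raises(ValueError, match="onset"):
            rs.sleep_onset_agreement(["WAKE"] * 30, ["NREM"] * 30)

    def test_randomized_against_direct_tally(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 80))
            ref = rng.choice(STAGES, size=n)
            pred = rng.choice(STAGES, size=n)
            if not np.isin(ref, ["REM", "NREM"]).any():
                continue
            out = rs.sleep_onset_agreement(ref, pred)
            onset = next(i for i, s in enumerate(ref) if s != "WAKE")
            lo, hi = max(0, onset - 10), min(n, onset + 11)
            tp = sum(
                ref[i] != "WAKE" and pred[i] != "WAKE" for i in range(lo, hi)
            )
            assert out["tp"] == tp
            assert out["n_compared"] == hi - lo


def _exact_mwu_p(a, b):
    """Exhaustive permutation p-value for the two-sided Mann-Whitney test."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    mu = n_a * len(b) / 2
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(idx) - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestRankTests:
    def test_identical_samples_no_shift(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = rs.rank_test_two_groups(a, a)
        assert p > 0.99

    def test_complete_separation_u_zero(self):
        u, _ = rs.rank_test_two_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            rs.rank_test_two_groups([], [1.0])

    def test_small_samples_match_permutation_enumeration(self, rng):
        for _ in range(25):
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 6))
            # continuous draws: ties have probability zero
            a = rng.normal(size=n_a)
            b = rng.normal(size=n_b) + rng.normal()
            _, p = rs.rank_test_two_groups(a, b)
            assert p == pytest.approx(_exact_mwu_p(a, b))

    def test_kruskal_identical_groups(self):
        h, p = rs.rank_test_k_groups([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_kruskal_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            rs.rank_test_k_groups([[1.0, 2.0]])

    def test_kruskal_matches_direct_formula(self, rng):
        for _ in range(50):
            groups = [rng.normal(size=int(rng.integers(3, 8))) for _ in range(3)]
            h, _ = rs.rank_test_k_groups(groups)
            pooled = np.concatenate(groups)
            ranks = stats.rankdata(pooled)
            n = len(pooled)
            start = 0
            h_direct = 0.0
            for g in groups:
                r = ranks[start:start + len(g)]
                h_direct += r.sum() ** 2 / len(g)
                start += len(g)
            h_direct = 12 / (n * (n + 1)) * h_direct - 3 * (n + 1)
            # tie correction (no ties in continuous draws)
            assert h == pytest.approx(h_direct)

    def test_two_group_consistency_with_mwu_decision(self, rng):
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(loc=rng.choice([0.0, 2.0]), size=12)
            _, p_h = rs.rank_test_k_groups([a, b])
            _, p_u = rs.rank_test_two_groups(a, b)
            assert (p_h <= 0.05) == (p_u <= 0.05)


class TestEvaluateCohort:
    @staticmethod
    def _events(n, duration_s, rng):
        starts = np.sort(rng.uniform(0, duration_s - 40, size=n))
        starts = starts[np.concatenate([[True], np.diff(starts) > 15]) ]
        evs = [rs.RespiratoryEvent(float(s), 12.0, "apnea") for s in starts]
        return rs.RespiratoryEventList(evs, duration_s)

    def test_perfect_prediction(self, rng):
        cohort = []
        for seed in range(4):
            hyp = rs.simulate_hypnogram(
                rs.DEFAULT_TRANSITION_MATRIX, 100, seed=seed
            )
            events = self._events(5, 100 * 30.0, rng)
            cohort.append((hyp, hyp, events, 50.0))
        rep = rs.evaluate_cohort(cohort)
        assert rep.kappa == 1.0
        assert rep.metric_agreement["tst"]["bias"] == 0.0
        for g in (1, 2, 3, 4):
            if rep.group_accuracy[g]["n"]:
                assert rep.group_accuracy[g]["sensitivity"] == 1.0
        assert rep.onset["f1"] == 1.0

    def test_single_subject_correlations_undefined(self, rng):
        hyp = rs.simulate_hypnogram(rs.DEFAULT_TRANSITION_MATRIX, 60, seed=3)
        rep = rs.evaluate_cohort([(hyp, hyp, self._events(2, 1800.0, rng), 30.0)])
        assert rep.metric_agreement["tst"]["pearson_r"] is None
        assert len(rep.subjects) == 1

    def test_pooled_confusion_total(self, rng):
        cohort = []
        total = 0
        for seed in range(3):
            n = 50 + 10 * seed
            ref = rs.simulate_hypnogram(rs.DEFAULT_TRANSITION_MATRIX, n, seed=seed)
            pred = rs.simulate_hypnogram(
                rs.DEFAULT_TRANSITION_MATRIX, n, seed=seed + 100
            )
            total += n
            cohort.append((ref, pred, self._events(2, n * 30.0, rng), n * 0.5))
        rep = rs.evaluate_cohort(cohort)
        assert rep.confusion.total == total
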