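"""Evaluation statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import spinefat.metrics as m
from spinefat.errors import ValidationError
from spinefat.io_dixon import MaskVolume


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------

def oracle_confusion(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def oracle_auc_pairs(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_pr_auc_threshold_sweep(scores, labels):
    thresholds = np.unique(scores)[::-1]
    recall_prev, area = 0.0, 0.0
    n_pos = labels.sum()
    for th in thresholds:
        sel = scores >= th
        tp = int((labels[sel] == 1).sum())
        fp = int((labels[sel] == 0).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - recall_prev) * precision
        recall_prev = recall
    return area


def oracle_kappa(a, b):
    n = len(a)
    p_o = sum(1 for x, y in zip(a, b) if x == y) / n
    classes = sorted(set(a) | set(b))
    p_e = sum(
        (sum(1 for x in a if x == c) / n) * (sum(1 for y in b if y == c) / n)
        for c in classes
    )
    return (p_o - p_e) / (1 - p_e), p_o, p_e


# ---------------------------------------------------------------------------
# confusion counts and overlap
# ---------------------------------------------------------------------------

class TestConfusionCounts:
    def test_perfect_agreement(self):
        t = np.zeros((1, 10, 10), dtype=np.uint8)
        t[0, :3, :10] = 1  # 30 positive of 100
        c = m.confusion_counts(MaskVolume(t), MaskVolume(t), scope="all_slices")
        assert (c.tp, c.fp, c.fn, c.tn) == (30, 0, 0, 70)

    def test_complement_prediction(self):
        t = np.zeros((1, 8, 8), dtype=np.uint8)
        t[0, :4] = 1
        c = m.confusion_counts(MaskVolume(1 - t), MaskVolume(t), scope="all_slices")
        assert c.tp == 0 and c.tn == 0

    def test_scope_drops_vertebra_free_slices(self):
        t = np.zeros((3, 4, 4), dtype=np.uint8)
        t[1, 1, 1] = 1
        p = np.ones((3, 4, 4), dtype=np.uint8)
        c = m.confusion_counts(MaskVolume(p), MaskVolume(t), scope="vertebra_slices_only")
        assert c.total == 16  # only slice 1 tallied
        c_all = m.confusion_counts(MaskVolume(p), MaskVolume(t), scope="all_slices")
        assert c_all.total == 48

    @pytest.mark.parametrize("seed", range(6))
    def test_random_masks_match_per_pixel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = (rng.random((2, 12, 12)) > 0.5).astype(np.uint8)
        t = (rng.random((2, 12, 12)) > 0.7).astype(np.uint8)
        c = m.confusion_counts(MaskVolume(p), MaskVolume(t), scope="all_slices")
        assert (c.tp, c.fp, c.fn, c.tn) == oracle_confusion(p, t)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            m.confusion_counts(np.zeros((1, 2, 2)), np.zeros((1, 3, 2)))


class TestOverlapScores:
    def test_identity(self):
        dsc, iou = m.overlap_scores(m.ConfusionCounts(30, 0, 0, 70))
        assert dsc == 1.0 and iou == 1.0

    def test_hand_computed_example(self):
        """TP=2, FP=1, FN=1: DSC = 4/6, IoU = 2/4 (explicit 4-pixel overlap)."""
        # explicit sets: X = {a, b, c}, Y = {a, b, d} -> |X∩Y| = 2
        dsc, iou = m.overlap_scores(m.ConfusionCounts(2, 1, 1, 0))
        assert dsc == pytest.approx(2 * 2 / 6)
        assert iou == pytest.approx(0.5)

    def test_empty_union_convention(self):
        dsc, iou = m.overlap_scores(m.ConfusionCounts(0, 0, 0, 50))
        assert dsc == 1.0 and iou == 1.0

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    def test_dsc_iou_f1_identities(self, tp, fp, fn):
        """DSC = 2 IoU/(1+IoU) and DSC = F1 for every confusion table."""
        counts = m.ConfusionCounts(tp, fp, fn, 10)
        dsc, iou = m.overlap_scores(counts)
        assert dsc == pytest.approx(2 * iou / (1 + iou), rel=1e-12)
        scores = m.classification_scores(counts)
        if tp + fp > 0 and tp + fn > 0 and not np.isnan(scores["f1"]):
            assert scores["f1"] == pytest.approx(dsc, rel=1e-12)


class TestClassificationScores:
    def test_perfect(self):
        s = m.classification_scores(m.ConfusionCounts(10, 0, 0, 90))
        assert all(v == 1.0 for v in s.values())

    def test_hand_computed(self):
        s = m.classification_scores(m.ConfusionCounts(8, 5, 2, 85))
        assert s["sensitivity"] == pytest.approx(0.8)
        assert s["specificity"] == pytest.approx(85 / 90, abs=1e-4)
        assert s["precision"] == pytest.approx(8 / 13, abs=1e-4)
        assert s["accuracy"] == pytest.approx(0.93)
        assert s["f1"] == pytest.approx(2 * (8 / 13) * 0.8 / (8 / 13 + 0.8), abs=1e-4)

    def test_zero_denominator_is_nan(self):
        s = m.classification_scores(m.ConfusionCounts(0, 0, 0, 10))
        assert np.isnan(s["sensitivity"]) and np.isnan(s["precision"])


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

class TestCohenKappa:
    def test_identical_raters(self):
        a = np.array([0, 1, 0, 1, 1])
        k, p_o, _ = m.cohen_kappa(a, a)
        assert k == pytest.approx(1.0)
        assert p_o == 1.0

    def test_hand_computed_example(self):
        """a=[1,1,0,0,1], b=[1,0,0,0,1]: p_o=0.8, p_e=0.48, kappa=0.6154."""
        k, p_o, p_e = m.cohen_kappa([1, 1, 0, 0, 1], [1, 0, 0, 0, 1])
        assert p_o == pytest.approx(0.8)
        assert p_e == pytest.approx(0.48)
        assert k == pytest.approx((0.8 - 0.48) / 0.52, rel=1e-6)

    def test_independent_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 20000)
        b = rng.integers(0, 2, 20000)
        k, _, _ = m.cohen_kappa(a, b)
        assert abs(k) < 0.03

    def test_linear_weighting_degenerate_for_two_classes(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 500)
        b = rng.integers(0, 2, 500)
        k_u, _, _ = m.cohen_kappa(a, b, weighting="none")
        k_l, _, _ = m.cohen_kappa(a, b, weighting="linear")
        assert k_u == pytest.approx(k_l, rel=1e-12)

    def test_both_constant_equal(self):
        k, _, _ = m.cohen_kappa([1, 1, 1], [1, 1, 1])
        assert k == 1.0

    def test_both_constant_different(self):
        with pytest.warns(UserWarning):
            k, _, _ = m.cohen_kappa([0, 0, 0], [1, 1, 1])
        assert k == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_contingency_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 2, 200))
        k, p_o, p_e = m.cohen_kappa(a, b)
        ok, op_o, op_e = oracle_kappa(list(a), list(b))
        assert (k, p_o, p_e) == pytest.approx((ok, op_o, op_e), rel=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 300)
        b = np.where(rng.random(300) < 0.8, a, 1 - a)
        k, _, _ = m.cohen_kappa(a, b)
        assert k == pytest.approx(cohen_kappa_score(a, b), rel=1e-10)


# ---------------------------------------------------------------------------
# ROC / PR AUC
# ---------------------------------------------------------------------------

class TestRocAucDelong:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        auc, lo, hi = m.roc_auc_delong(scores, labels)
        assert auc == 1.0 and hi == 1.0

    def test_constant_scores_give_half(self):
        auc, _, _ = m.roc_auc_delong(np.ones(20), np.r_[np.zeros(10), np.ones(10)])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            m.roc_auc_delong(np.arange(5.0), np.ones(5))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 200)
        scores = np.round(rng.normal(labels.astype(float), 1.2), 1)  # rounding makes ties
        auc, _, _ = m.roc_auc_delong(scores, labels)
        assert auc == pytest.approx(oracle_auc_pairs(scores, labels), rel=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 150)
        scores = rng.normal(labels.astype(float), 1.0)
        a1, l1, h1 = m.roc_auc_delong(scores, labels)
        a2, l2, h2 = m.roc_auc_delong(np.exp(scores / 3), labels)
        assert (a1, l1, h1) == pytest.approx((a2, l2, h2), rel=1e-12)

    def test_delong_se_close_to_bootstrap(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, 300)
        scores = rng.normal(labels.astype(float), 1.0)
        auc, lo, hi = m.roc_auc_delong(scores, labels)
        se = (hi - lo) / (2 * 1.96)
        boot = []
        for _ in range(500):
            idx = rng.integers(0, 300, 300)
            if labels[idx].min() == labels[idx].max():
                continue
            boot.append(oracle_auc_rank(scores[idx], labels[idx]))
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.25)


def oracle_auc_rank(scores, labels):
    from scipy.stats import rankdata

    r = rankdata(scores)
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    return (r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestPrAuc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        assert m.pr_auc(scores, labels) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(5)
        labels = (rng.random(20000) < 0.3).astype(int)
        scores = rng.random(20000)
        assert m.pr_auc(scores, labels) == pytest.approx(0.3, abs=0.02)

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            m.pr_auc(np.arange(5.0), np.zeros(5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_threshold_sweep(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 50)
        labels[0] = 1
        scores = np.round(rng.normal(labels.astype(float), 1.0), 1)  # with ties
        assert m.pr_auc(scores, labels) == pytest.approx(
            oracle_pr_auc_threshold_sweep(scores, labels), rel=1e-12
        )

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 400)
        scores = rng.normal(labels.astype(float), 1.5)
        assert m.pr_auc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), rel=1e-10
        )


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_pairs(self):
        pairs = [(30.0, 30.0), (40.0, 40.0), (35.0, 35.0)]
        r = m.bland_altman(pairs)
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_hand_computed_differences(self):
        """Differences exactly {-1, 0, 1}: bias 0, SD 1, LOA +/-1.96."""
        pairs = [(10.0, 11.0), (10.0, 10.0), (10.0, 9.0)]
        r = m.bland_altman(pairs)
        assert r.bias == pytest.approx(0.0)
        assert r.loa_low == pytest.approx(-1.96)
        assert r.loa_high == pytest.approx(1.96)

    def test_orientation_manual_minus_auto(self):
        # automatic reads higher -> negative bias
        pairs = [(30.0, 31.0), (32.0, 33.5), (35.0, 35.5)]
        assert m.bland_altman(pairs).bias < 0

    def test_monte_carlo_consistency(self):
        """n=5000 Normal(-0.6, 1.36) differences recover bias and LOA."""
        rng = np.random.default_rng(123)
        mu, sigma, n = -0.6, 1.36, 5000
        base = 30 + 5 * rng.random(n)
        d = rng.normal(mu, sigma, n)
        r = m.bland_altman(np.column_stack([base, base - d]))
        assert r.bias == pytest.approx(mu, abs=0.05)
        assert r.loa_low == pytest.approx(mu - 1.96 * sigma, abs=0.08)
        assert r.loa_high == pytest.approx(mu + 1.96 * sigma, abs=0.08)
        assert r.bias_ci[0] < mu < r.bias_ci[1]

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            m.bland_altman([(1.0, 1.0), (2.0, 2.0)])

    @given(shift=st.floats(-10, 10), seed=st.integers(0, 100))
    def test_equivariance_under_shifts(self, shift, seed):
        rng = np.random.default_rng(seed)
        pairs = 30 + rng.random((10, 2))
        r0 = m.bland_altman(pairs)
        # shifting both members leaves the bias unchanged
        r_both = m.bland_altman(pairs + shift)
        assert r_both.bias == pytest.approx(r0.bias, abs=1e-9)
        # shifting one member shifts the bias by exactly that constant
        shifted = pairs.copy()
        shifted[:, 0] += shift
        r_one = m.bland_altman(shifted)
        assert r_one.bias == pytest.approx(r0.bias + shift, abs=1e-9)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

class TestRepeatability:
    def _frames(self, t, r):
        idx = [f"s{i}" for i in range(len(t))]
        return (pd.DataFrame({"L1": t}, index=idx), pd.DataFrame({"L1": r}, index=idx))

    def test_identical_test_retest_icc_one(self):
        t = np.array([30.0, 35.0, 40.0, 28.0])
        test, retest = self._frames(t, t)
        r = m.repeatability(test, retest)
        assert r.icc == pytest.approx(1.0)
        assert r.precision_error_pct == 0.0

    def test_two_point_cv_hand_arithmetic(self):
        """Pair (30, 31): CV = (|d|/sqrt(2)) / 30.5 * 100 = 2.318%."""
        cv = m.precision_error_rms_cv(np.array([30.0]), np.array([31.0]))
        assert cv == pytest.approx((1 / np.sqrt(2)) / 30.5 * 100, rel=1e-6)
        assert cv == pytest.approx(2.318, abs=0.001)

    def test_icc_recovers_variance_components(self):
        """ICC -> sigma_b^2/(sigma_b^2 + sigma_w^2) for simulated pairs."""
        rng = np.random.default_rng(42)
        sigma_b, sigma_w, n = 6.0, 2.0, 500
        subject = rng.normal(33.0, sigma_b, n)
        t = subject + rng.normal(0, sigma_w, n)
        r = subject + rng.normal(0, sigma_w, n)
        icc = m.icc_absolute_agreement(t, r)
        expect = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        assert icc == pytest.approx(expect, abs=0.02)

    def test_matches_pingouin_icc2(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        n = 40
        subject = rng.normal(33, 5, n)
        t = subject + rng.normal(0, 1.5, n)
        r = subject + rng.normal(0, 1.5, n)
        icc = m.icc_absolute_agreement(t, r)
        long = pd.DataFrame({
            "subject": np.r_[np.arange(n), np.arange(n)],
            "rater": ["a"] * n + ["b"] * n,
            "score": np.r_[t, r],
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        expect = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc == pytest.approx(expect, rel=1e-8)

    def test_unpaired_entries_rejected(self):
        test = pd.DataFrame({"L1": [30.0, 31.0]}, index=["a", "b"])
        retest = pd.DataFrame({"L1": [30.0, 31.0]}, index=["a", "c"])
        with pytest.raises(ValidationError, match="unpaired"):
            m.repeatability(test, retest)

    def test_per_level_and_pooled_reported(self):
        rng = np.random.default_rng(5)
        idx = [f"s{i}" for i in range(8)]
        cols = ["L1", "L2", "L3"]
        base = pd.DataFrame(rng.normal(33, 5, (8, 3)), index=idx, columns=cols)
        retest = base + rng.normal(0, 0.5, (8, 3))
        r = m.repeatability(base, retest)
        assert set(r.per_level) == set(cols)
        assert r.n_pairs == 24
        assert 0 < r.icc <= 1
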