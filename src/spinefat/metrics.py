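"""Segmentation and agreement statistics.

Everything the pipeline's evaluation battery needs: pixel confusion counts
(optionally scoped to slices where the reference segmentation is present),
Dice/IoU overlap, classification scores, Cohen's kappa with per-annotator
chance agreement, ROC AUC with DeLong structural-component variance, the
step-wise precision-recall AUC, Bland-Altman limits of agreement, and
test-retest repeatability (ICC(2,1) plus the RMS-CV short-term precision
error).

Conventions worth noting:

* DSC and IoU are related by ``DSC = 2*IoU/(1+IoU)`` and DSC equals the F1
  score when both are computed from the same confusion counts.
* Bland-Altman differences are oriented ``reference - comparison`` (manual
  minus automatic): a negative bias means the automatic method reads higher.
* ICC uses the two-way random-effects, absolute-agreement, single-measure
  form; the short-term precision error is the RMS over pairs of the
  two-point coefficient of variation (pair SD = |difference| / sqrt(2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_dixon import MaskVolume


# ---------------------------------------------------------------------------
# confusion counts and derived scores
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    scope: str = "all_slices"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    pred: MaskVolume | np.ndarray,
    truth: MaskVolume | np.ndarray,
    scope: Literal["vertebra_slices_only", "all_slices"] = "vertebra_slices_only",
) -> ConfusionCounts:
    """Pixel TP/FP/FN/TN tallies between two binary masks.

    With ``scope="vertebra_slices_only"`` only slices where the reference
    mask contains at least one positive pixel are tallied — the scope in
    which segmentation performance is normally reported, since most sagittal
    slices contain no vertebrae at all.
    """
    p = pred.data if isinstance(pred, MaskVolume) else np.asarray(pred)
    t = truth.data if isinstance(truth, MaskVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    if scope == "vertebra_slices_only" and p.ndim == 3:
        keep = t.any(axis=(1, 2))
        p, t = p[keep], t[keep]
    elif scope not in ("vertebra_slices_only", "all_slices"):
        raise ValidationError(f"unknown scope {scope!r}")
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = int(np.logical_and(~p, ~t).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, scope=scope)


def overlap_scores(counts: ConfusionCounts) -> tuple[float, float]:
    """(DSC, IoU) from confusion counts.

    ``DSC = 2TP/(2TP+FP+FN)``, ``IoU = TP/(TP+FP+FN)``.  When both masks are
    empty in scope the overlap is perfect by convention (1, 1).
    """
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0, 1.0
    iou = counts.tp / denom
    dsc = 2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
    return dsc, iou


def classification_scores(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision, F1 and accuracy from counts.

    Scores whose denominator is zero are reported as NaN.
    """
    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    acc = _ratio(counts.tp + counts.tn, counts.total)
    # computed from counts, not as the harmonic mean, so TP=0 gives 0 (= DSC)
    # rather than the 0/0 indeterminate of precision/recall
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "accuracy": acc,
    }


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def cohen_kappa(
    labels_a: Sequence[int] | np.ndarray,
    labels_b: Sequence[int] | np.ndarray,
    weighting: Literal["none", "linear"] = "none",
) -> tuple[float, float, float]:
    """Cohen's kappa with per-annotator empirical chance agreement.

    Returns ``(kappa, p_o, p_e)`` where ``kappa = (p_o - p_e)/(1 - p_e)``;
    the expected agreement ``p_e`` is the sum over classes of the product of
    the two annotators' marginal label frequencies.  For two classes linear
    weighting coincides with the unweighted statistic.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValidationError("label vectors must have equal length")
    classes, a_idx = np.unique(a, return_inverse=True)
    classes_b, b_idx = np.unique(b, return_inverse=True)
    all_classes = np.union1d(classes, classes_b)
    k = len(all_classes)
    lookup = {c: i for i, c in enumerate(all_classes)}
    ai = np.array([lookup[v] for v in a])
    bi = np.array([lookup[v] for v in b])
    n = len(a)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    table /= n
    pa = table.sum(axis=1)
    pb = table.sum(axis=0)

    if weighting == "none":
        w = 1.0 - np.eye(k)
    elif weighting == "linear":
        idx = np.arange(k)
        w = np.abs(idx[:, None] - idx[None, :]) / max(k - 1, 1)
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")

    p_o = float(np.diag(table).sum())
    p_e = float((pa[:, None] * pb[None, :] * np.eye(k)).sum())
    disagreement_o = float((w * table).sum())
    disagreement_e = float((w * pa[:, None] * pb[None, :]).sum())

    both_constant = pa.max() == 1.0 and pb.max() == 1.0
    if disagreement_e == 0:
        # both raters constant and equal: perfect agreement by convention
        if p_o == 1.0:
            return 1.0, p_o, p_e
        warnings.warn("both raters constant but unequal; kappa defined as 0", stacklevel=2)
        return 0.0, p_o, p_e
    if both_constant:
        warnings.warn("both raters constant but unequal; kappa defined as 0", stacklevel=2)
        return 0.0, p_o, p_e
    kappa = 1.0 - disagreement_o / disagreement_e
    return float(kappa), p_o, p_e


# ---------------------------------------------------------------------------
# ROC AUC with DeLong variance, PR AUC
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_delong(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """ROC AUC with a 95% CI from DeLong's structural-component variance.

    The AUC is the normalised Mann-Whitney statistic (ties credited 1/2).
    The standard error comes from the empirical variances of the per-positive
    and per-negative structural components; the CI is ``auc +/- 1.96*SE``,
    clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise ValidationError("both classes must be present")
    pos, neg = s[y], s[~y]
    rank_all = _midranks(s)
    rank_pos = _midranks(pos)
    rank_neg = _midranks(neg)
    # structural components: V10[i] = P(X_i > Y) + P(X_i = Y)/2 etc.
    v10 = (rank_all[y] - rank_pos) / n
    v01 = 1.0 - (rank_all[~y] - rank_neg) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return auc, lo, hi


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, step-wise interpolation.

    The curve is traversed from high to low threshold; each block of tied
    scores contributes ``(R_i - R_{i-1}) * P_i`` with the precision *at* that
    operating point (no precision envelope is applied), i.e. the
    average-precision summation.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValidationError("no positive labels")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order].astype(np.float64)
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1.0 - y_sorted)
    # operating points only at the end of each tied-score block
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp_b, fp_b = tp[distinct], fp[distinct]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

@dataclass
class BlandAltmanResult:
    pairs: np.ndarray           # (n, 2): reference (manual), comparison (auto)
    bias: float                 # mean(reference - comparison)
    bias_ci: tuple[float, float]
    loa_low: float
    loa_high: float
    pct_outside: float          # fraction of differences outside the LOA, in %

    @property
    def differences(self) -> np.ndarray:
        return self.pairs[:, 0] - self.pairs[:, 1]

    @property
    def means(self) -> np.ndarray:
        return self.pairs.mean(axis=1)


def bland_altman(pairs: Sequence[tuple[float, float]] | np.ndarray) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement.

    ``pairs`` holds (manual, automatic) measurements; differences are
    ``manual - automatic``.  LOA = bias +/- 1.96 * sample SD (n-1
    denominator); the bias CI is ``bias +/- 1.96 * SD/sqrt(n)``.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need >= 3 (manual, automatic) pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    half_ci = 1.96 * sd / np.sqrt(len(d))
    outside = np.sum((d < loa_low) | (d > loa_high))
    return BlandAltmanResult(
        pairs=arr,
        bias=bias,
        bias_ci=(bias - half_ci, bias + half_ci),
        loa_low=loa_low,
        loa_high=loa_high,
        pct_outside=100.0 * float(outside) / len(d),
    )


# ---------------------------------------------------------------------------
# test-retest repeatability
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    icc: float
    precision_error_pct: float
    n_pairs: int
    per_level: dict[str, "RepeatabilityResult"] = field(default_factory=dict)


def icc_absolute_agreement(test: np.ndarray, retest: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the paired-measurement ANOVA decomposition with k = 2
    occasions.  Identical test and retest columns (with between-subject
    spread) give exactly 1.
    """
    x = np.column_stack([np.asarray(test, dtype=np.float64),
                         np.asarray(retest, dtype=np.float64)])
    n, k = x.shape
    if n < 2:
        raise ValidationError("need >= 2 subjects for an ICC")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 0.0
    return float((msr - mse) / denom)


def precision_error_rms_cv(test: np.ndarray, retest: np.ndarray) -> float:
    """Short-term precision error: RMS over pairs of the two-point CV, in %.

    For each pair the SD is ``|test - retest| / sqrt(2)`` and the CV is
    ``SD / mean * 100``; the summary is the root mean square of the CVs.
    """
    t = np.asarray(test, dtype=np.float64)
    r = np.asarray(retest, dtype=np.float64)
    sd = np.abs(t - r) / np.sqrt(2.0)
    mean = (t + r) / 2.0
    if np.any(mean == 0):
        raise ValidationError("pair mean of zero: CV undefined")
    cv = sd / mean * 100.0
    return float(np.sqrt(np.mean(cv**2)))


def repeatability(
    test: pd.DataFrame, retest: pd.DataFrame
) -> RepeatabilityResult:
    """Pooled and per-level repeatability of paired BMF measurements.

    ``test`` and ``retest`` are wide tables (rows = subjects, columns =
    levels) that must share index and columns; unpaired entries are an
    error.
    """
    missing = set(test.index).symmetric_difference(retest.index)
    missing |= set(test.columns).symmetric_difference(retest.columns)
    if missing:
        raise ValidationError(f"unpaired test/retest entries: {sorted(map(str, missing))}")
    test = test.sort_index().sort_index(axis=1)
    retest = retest.sort_index().sort_index(axis=1)
    if test.isna().any().any() or retest.isna().any().any():
        raise ValidationError("missing measurements in test/retest tables")

    t_all = test.to_numpy().ravel()
    r_all = retest.to_numpy().ravel()
    pooled = RepeatabilityResult(
        icc=icc_absolute_agreement(t_all, r_all),
        precision_error_pct=precision_error_rms_cv(t_all, r_all),
        n_pairs=t_all.size,
    )
    for level in test.columns:
        t = test[level].to_numpy()
        r = retest[level].to_numpy()
        pooled.per_level[str(level)] = RepeatabilityResult(
            icc=icc_absolute_agreement(t, r),
            precision_error_pct=precision_error_rms_cv(t, r),
            n_pairs=t.size,
        )
    return pooled
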