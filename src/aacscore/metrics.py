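"""Agreement and classification statistics for predicted vs. manual AACS.

The battery compares automated total calcification scores against manual
ground truth: ICC(2,1) for absolute agreement, MAE / R^2 / Spearman for fit,
Bland-Altman bias and limits of agreement, a Bonferroni-corrected Wilcoxon
matched-pairs test, nonparametric TOST equivalence at margins of 1 and 0.5
points, one-vs-rest severity classification rates, and the boundary
distance error (BDE) of severity misclassifications.

Conventions fixed here: differences are prediction minus ground truth; R^2
is computed on the identity relationship (1 - SS_res/SS_tot about the
ground-truth mean, residuals pred - gt), not a refitted line; multiclass
sensitivity/specificity/PPV/NPV are macro-averaged one-vs-rest with
zero-denominator classes excluded (with a warning); TOST uses two one-sided
Wilcoxon signed-rank tests of the shifted differences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .kauppila import SEVERITY_CLASSES, severity_class


@dataclass(frozen=True)
class PairedScores:
    pred: np.ndarray
    gt: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pred, dtype=float)
        g = np.asarray(self.gt, dtype=float)
        if p.shape != g.shape or p.ndim != 1:
            raise ValueError("pred and gt must be equal-length 1-D sequences")
        object.__setattr__(self, "pred", p)
        object.__setattr__(self, "gt", g)

    @property
    def n(self) -> int:
        return len(self.pred)

    @property
    def diffs(self) -> np.ndarray:
        return self.pred - self.gt


@dataclass(frozen=True)
class ClassificationReport:
    confusion: np.ndarray  # 3x3, rows = truth, cols = prediction
    acc: float             # percentages
    sn: float
    sp: float
    ppv: float
    npv: float

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(), "acc": self.acc,
                "sn": self.sn, "sp": self.sp, "ppv": self.ppv,
                "npv": self.npv}


@dataclass(frozen=True)
class AgreementReport:
    n: int
    mae: float
    r2: float
    spearman_rho: float
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    wilcoxon_p: float
    wilcoxon_significant: bool
    tost_pass_1: bool
    tost_pass_05: bool
    classification: ClassificationReport
    mean_bde: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classification"] = self.classification.to_dict()
        d["icc_ci"] = list(self.icc_ci)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        c = self.classification
        lines = [
            f"n                 {self.n}",
            f"Spearman rho      {self.spearman_rho:.3f}",
            f"ICC(2,1)          {self.icc:.3f} "
            f"(95% CI {self.icc_ci[0]:.3f}, {self.icc_ci[1]:.3f})",
            f"R^2               {self.r2:.3f}",
            f"MAE               {self.mae:.3f}",
            f"Bias (pred-GT)    {self.bias:.3f} "
            f"(LoA {self.loa_low:.3f}, {self.loa_high:.3f})",
            f"Wilcoxon p        {self.wilcoxon_p:.4f}"
            f"{' *' if self.wilcoxon_significant else ''}",
            f"TOST equiv  D=1   {'yes' if self.tost_pass_1 else 'no'}",
            f"TOST equiv  D=0.5 {'yes' if self.tost_pass_05 else 'no'}",
            f"ACC/SN/SP         {c.acc:.2f} / {c.sn:.2f} / {c.sp:.2f}",
            f"PPV/NPV           {c.ppv:.2f} / {c.npv:.2f}",
            f"Mean BDE          {self.mean_bde:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# agreement

def icc_2_1(pairs: PairedScores, alpha: float = 0.05
            ) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Treats (gt, pred) as two raters of n subjects.  From the two-way ANOVA
    decomposition with k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The confidence interval is the standard F-based construction.
    """
    if pairs.n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    x = np.column_stack([pairs.gt, pairs.pred])  # n subjects x k raters
    n, k = x.shape
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
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong): pivot on MSR/MSE with the non-centrality
    # correction for the column effect
    if mse == 0:
        return float(icc), (float(icc), float(icc))
    a = (k * icc) / (n * (1 - icc)) if icc != 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc != 1 else np.inf
    v_num = (a * msc + b * mse) ** 2
    v_den = ((a * msc) ** 2 / (k - 1)
             + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    v = v_num / v_den if np.isfinite(v_num) and v_den > 0 else (n - 1)
    f_obs = msr / mse
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (f_obs - f_l) / (f_l * (k * msc / mse + k * n - k - n)
                                 + n * f_obs)
    upper = n * (f_u * f_obs - 1) / (k * msc / mse + k * n - k - n
                                     + n * f_u * f_obs)
    return float(icc), (float(lower), float(upper))


def regression_fit_metrics(pairs: PairedScores
                           ) -> tuple[float, float, float]:
    """(MAE, R^2, Spearman rho) of predictions against ground truth."""
    if pairs.n < 2:
        raise ValueError("need at least 2 pairs")
    mae = float(np.mean(np.abs(pairs.diffs)))
    ss_tot = float(np.sum((pairs.gt - pairs.gt.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant ground truth: R^2 undefined")
    r2 = 1.0 - float(np.sum(pairs.diffs ** 2)) / ss_tot
    rho = float(stats.spearmanr(pairs.pred, pairs.gt).statistic)
    return mae, r2, rho


def bland_altman(pairs: PairedScores) -> tuple[float, float, float]:
    """(bias, lower, upper): mean difference and 95% limits of agreement.

    Differences are pred - gt; limits are bias +/- 1.96 x sample SD (n-1).
    """
    if pairs.n < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.diffs
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_tests(pairs: PairedScores, alpha: float = 0.05,
                 n_comparisons: int = 3) -> tuple[float, bool, float]:
    """Two-sided Wilcoxon signed-rank test with Bonferroni threshold.

    Returns (p, significant, threshold) with threshold = alpha /
    n_comparisons.  Zero differences are dropped; if every difference is
    zero, p = 1 by convention (flagged via a warning).
    """
    if pairs.n < 6:
        raise ValueError("need at least 6 pairs for a meaningful test")
    d = pairs.diffs
    threshold = alpha / n_comparisons
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p set to 1")
        return 1.0, False, threshold
    p = float(stats.wilcoxon(d, zero_method="wilcox",
                             alternative="two-sided").pvalue)
    return p, p < threshold, threshold


def tost_equivalence(pairs: PairedScores, delta: float,
                     alpha: float = 0.05) -> tuple[bool, float, float]:
    """Nonparametric TOST: equivalence of pred and gt within +/- delta.

    Runs two one-sided Wilcoxon signed-rank tests of the differences
    shifted by -delta (alternative: less) and +delta (alternative:
    greater); equivalence is declared iff both one-sided p < alpha.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if pairs.n < 6:
        raise ValueError("need at least 6 pairs")
    d = pairs.diffs

    def one_sided(shifted: np.ndarray, alternative: str) -> float:
        if np.all(shifted == 0):
            return 0.5
        return float(stats.wilcoxon(shifted, zero_method="wilcox",
                                    alternative=alternative).pvalue)

    p_upper = one_sided(d - delta, "less")     # H1: median diff < +delta
    p_lower = one_sided(d + delta, "greater")  # H1: median diff > -delta
    return (p_upper < alpha and p_lower < alpha), p_lower, p_upper


# ---------------------------------------------------------------------------
# severity classification

def boundary_distance_error(pred_total: float, gt_total: float) -> float:
    """Distance from a misclassified prediction to the true severity bin.

    Zero when the severity classes agree; otherwise the minimum |pred - s|
    over integer scores s inside the ground-truth class's interval.
    """
    intervals = {"no_mild": (0, 4), "moderate": (5, 15), "severe": (16, 24)}
    pred_cls = severity_class(int(round(pred_total)))
    gt_cls = severity_class(int(round(gt_total)))
    if pred_cls == gt_cls:
        return 0.0
    lo, hi = intervals[gt_cls]
    return float(min(abs(pred_total - s) for s in range(lo, hi + 1)))


def classification_report(pairs: PairedScores) -> ClassificationReport:
    """3x3 severity confusion matrix and macro one-vs-rest rates (percent)."""
    idx = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    confusion = np.zeros((3, 3), dtype=int)
    for p, g in zip(pairs.pred, pairs.gt):
        confusion[idx[severity_class(int(round(g)))],
                  idx[severity_class(int(round(p)))]] += 1
    n = confusion.sum()
    acc = 100.0 * np.trace(confusion) / n

    def macro(rate_fn) -> float:
        vals = []
        for c in range(3):
            tp = confusion[c, c]
            fn = confusion[c].sum() - tp
            fp = confusion[:, c].sum() - tp
            tn = n - tp - fn - fp
            v = rate_fn(tp, fp, fn, tn)
            if v is None:
                warnings.warn(
                    f"class {SEVERITY_CLASSES[c]}: zero denominator, "
                    "excluded from the macro average")
            else:
                vals.append(v)
        return 100.0 * float(np.mean(vals)) if vals else float("nan")

    sn = macro(lambda tp, fp, fn, tn: tp / (tp + fn) if tp + fn else None)
    sp = macro(lambda tp, fp, fn, tn: tn / (tn + fp) if tn + fp else None)
    ppv = macro(lambda tp, fp, fn, tn: tp / (tp + fp) if tp + fp else None)
    npv = macro(lambda tp, fp, fn, tn: tn / (tn + fn) if tn + fn else None)
    return ClassificationReport(confusion=confusion, acc=float(acc),
                                sn=sn, sp=sp, ppv=ppv, npv=npv)


def mean_bde(pairs: PairedScores) -> float:
    """Mean boundary distance error over misclassified samples only (0 if none)."""
    errs = [boundary_distance_error(p, g)
            for p, g in zip(pairs.pred, pairs.gt)]
    mis = [e for e in errs if e > 0]
    return float(np.mean(mis)) if mis else 0.0


def evaluate(pairs: PairedScores, alpha: float = 0.05,
             n_comparisons: int = 3) -> AgreementReport:
    """Run the full agreement battery on one prediction/ground-truth set."""
    if pairs.n < 6:
        raise ValueError("need at least 6 pairs for the full battery")
    mae, r2, rho = regression_fit_metrics(pairs)
    icc, ci = icc_2_1(pairs)
    bias, lo, hi = bland_altman(pairs)
    p, sig, _ = paired_tests(pairs, alpha, n_comparisons)
    tost1, _, _ = tost_equivalence(pairs, 1.0, alpha)
    tost05, _, _ = tost_equivalence(pairs, 0.5, alpha)
    return AgreementReport(
        n=pairs.n, mae=mae, r2=r2, spearman_rho=rho, icc=icc, icc_ci=ci,
        bias=bias, loa_low=lo, loa_high=hi, wilcoxon_p=p,
        wilcoxon_significant=sig, tost_pass_1=tost1, tost_pass_05=tost05,
        classification=classification_report(pairs), mean_bde=mean_bde(pairs))


def bootstrap_ci(values_fn, pairs: PairedScores, n_resamples: int = 2000,
                 seed: int = 0, alpha: float = 0.05
                 ) -> tuple[float, float]:
    """Percentile bootstrap CI of a scalar statistic of a PairedScores set."""
    rng = np.random.default_rng(seed)
    stats_ = []
    for _ in range(n_resamples):
        idx = rng.integers(0, pairs.n, pairs.n)
        try:
            stats_.append(values_fn(PairedScores(pairs.pred[idx],
                                                 pairs.gt[idx])))
        except ValueError:
            continue
    lo, hi = np.percentile(stats_, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
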