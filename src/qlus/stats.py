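"""Diagnostic-accuracy statistics against a reference standard.

Implements the evaluation battery for binary imaging calls judged against
CT: 2x2 confusion matrices and their standard metrics, Cohen's
chance-corrected kappa with the conventional qualitative bands, ROC analysis
with a strict ">" positivity rule, Mann-Whitney (midrank) AUC and the
Hanley-McNeil binomial standard error, Youden-index best-cutoff selection,
tie-corrected Spearman rank correlation, rank-based two-group tests, and
univariate logistic regression with separation diagnostics and a
Hosmer-Lemeshow goodness-of-fit check.

Conventions fixed here for table reproduction: a score is called positive
iff it is strictly above the threshold; rounded values use round-half-away;
Youden ties break toward the higher-specificity (higher) threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

from ._rounding import round_half_away

__all__ = [
    "ConfusionMatrix",
    "DiagnosticSummary",
    "KappaResult",
    "ROCCurve",
    "SpearmanResult",
    "RankTestResult",
    "LogisticFit",
    "confusion",
    "diagnostic_summary",
    "cohen_kappa",
    "combine_either",
    "roc_analysis",
    "spearman_rho",
    "rank_two_group_test",
    "signed_rank_test",
    "friedman_test",
    "univariate_logistic",
]


def _as_binary_array(labels, name: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of a binary method against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion(predicted, reference) -> ConfusionMatrix:
    """Cross-tabulate predicted binary calls against the reference standard."""
    pred = _as_binary_array(predicted, "predicted")
    ref = _as_binary_array(reference, "reference")
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("predicted and reference must be equal-length 1-D sequences")
    if pred.size == 0:
        raise ValueError("empty label sequences")
    return ConfusionMatrix(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Standard 2x2 metrics; a metric with a zero denominator is None (undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    kappa: float | None

    def rounded(self, decimals: int = 2) -> "DiagnosticSummary":
        r = lambda v: None if v is None else round_half_away(v, decimals)
        return DiagnosticSummary(
            r(self.sensitivity), r(self.specificity), r(self.ppv),
            r(self.npv), r(self.accuracy), r(self.kappa),
        )

    def as_percentages(self) -> dict:
        """sensitivity/specificity/accuracy on the 0-100 scale (abstract style)."""
        out = {}
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else 100.0 * v
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_summary(cm: ConfusionMatrix) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV, accuracy and kappa from a 2x2 table."""
    kappa = cohen_kappa(cm)
    return DiagnosticSummary(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.total,
        kappa=kappa.value,
    )


#: Qualitative agreement bands for kappa (Landis & Koch).
_KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class KappaResult:
    value: float | None
    band: str | None


def cohen_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Cohen's chance-corrected agreement, kappa = (po - pe) / (1 - pe).

    ``pe`` comes from the marginal products. If chance agreement is exactly 1
    (both marginals degenerate) kappa is undefined and flagged as None.
    """
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if pe == 1.0:
        return KappaResult(None, None)
    value = (po - pe) / (1.0 - pe)
    band = "poor"
    for upper, name in _KAPPA_BANDS:
        if value <= upper:
            band = name
            break
    if value <= 0:
        band = "poor"
    return KappaResult(value, band)


def combine_either(labels_a, labels_b) -> np.ndarray:
    """Elementwise OR of two binary call sequences (the 'either method' rule)."""
    a = _as_binary_array(labels_a, "labels_a")
    b = _as_binary_array(labels_b, "labels_b")
    if a.shape != b.shape:
        raise ValueError("label sequences must have equal length")
    return a | b


@dataclass(frozen=True)
class ROCCurve:
    """An empirical ROC over the observed score values (strict ">" rule)."""

    thresholds: np.ndarray  # unique observed scores, ascending
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    se: float
    best_cutoff: float
    best_youden: float

    def operating_point(self, threshold: float) -> tuple[float, float]:
        i = int(np.searchsorted(self.thresholds, threshold))
        if i == len(self.thresholds) or self.thresholds[i] != threshold:
            raise KeyError(f"{threshold} is not an observed threshold")
        return float(self.sensitivities[i]), float(self.specificities[i])


def roc_analysis(scores, reference) -> ROCCurve:
    """ROC analysis of a continuous score against a binary reference.

    Thresholds sweep the observed score values; at threshold t a subject is
    called positive iff its score is strictly greater than t. The area under
    the curve is computed by the rank (Mann-Whitney) construction with
    midrank tie handling, its standard error by the Hanley-McNeil binomial
    formula, and the best cutoff maximizes the Youden index
    J = sensitivity + specificity - 1, ties broken toward the higher
    threshold (higher specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary_array(reference, "reference")
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and reference must be equal-length 1-D sequences")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both reference classes must be present")

    thresholds = np.unique(s)
    # counts of scores > t within each class, via cumulative counts
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    tp = n1 - np.searchsorted(pos_sorted, thresholds, side="right")
    fp = n0 - np.searchsorted(neg_sorted, thresholds, side="right")
    sens = tp / n1
    spec = (n0 - fp) / n0

    ranks = sps.rankdata(s)  # midranks
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))

    youden = sens + spec - 1.0
    # argmax with ties broken toward the larger threshold (higher specificity)
    best_idx = len(youden) - 1 - int(np.argmax(youden[::-1]))
    return ROCCurve(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        se=float(se),
        best_cutoff=float(thresholds[best_idx]),
        best_youden=float(youden[best_idx]),
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float | None
    p_value: float | None
    n: int

    @property
    def undefined(self) -> bool:
        return self.rho is None


def spearman_rho(x, y) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with a two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D sequences of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(None, None, len(x))
    res = sps.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue), len(x))


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str


def rank_two_group_test(group_a, group_b) -> RankTestResult:
    """Two-sided rank-sum (Mann-Whitney) comparison of two independent groups.

    Uses the exact null distribution for small samples (total <= 25, no ties)
    and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 25 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def signed_rank_test(x, y=None) -> RankTestResult:
    """Wilcoxon signed-rank test for paired samples (or one sample of differences)."""
    res = sps.wilcoxon(x, y, alternative="two-sided")
    return RankTestResult(float(res.statistic), float(res.pvalue), "wilcoxon-signed-rank")


def friedman_test(*groups) -> RankTestResult:
    """Friedman test for three or more related samples."""
    if len(groups) < 3:
        raise ValueError("the Friedman test needs at least three related samples")
    res = sps.friedmanchisquare(*groups)
    return RankTestResult(float(res.statistic), float(res.pvalue), "friedman")


@dataclass(frozen=True)
class LogisticFit:
    """A univariate logistic fit on the log-odds scale, with diagnostics."""

    intercept: float | None
    beta: float | None
    beta_se: float | None
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    wald_p: float | None
    gof_statistic: float | None
    gof_df: int | None
    gof_p: float | None
    n: int
    converged: bool
    separation: bool
    message: str = ""


def _hosmer_lemeshow(y: np.ndarray, fitted: np.ndarray, n_groups: int = 10):
    """Hosmer-Lemeshow chi-square over risk-decile groups (fewer if ties force it)."""
    order = np.argsort(fitted, kind="mergesort")
    y_sorted = y[order].astype(float)
    p_sorted = fitted[order]
    # quantile bin edges on the fitted probabilities; duplicates collapse groups
    edges = np.unique(np.quantile(p_sorted, np.linspace(0, 1, n_groups + 1)[1:-1]))
    idx = np.searchsorted(edges, p_sorted, side="right")
    stat = 0.0
    g = 0
    for group in np.unique(idx):
        in_g = idx == group
        n_g = int(in_g.sum())
        obs1 = y_sorted[in_g].sum()
        exp1 = p_sorted[in_g].sum()
        exp0 = n_g - exp1
        if exp1 <= 0 or exp0 <= 0:
            continue
        stat += (obs1 - exp1) ** 2 / exp1 + ((n_g - obs1) - exp0) ** 2 / exp0
        g += 1
    df = max(g - 2, 1)
    return float(stat), df, float(sps.chi2.sf(stat, df))


def univariate_logistic(outcome, predictor, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood univariate logistic regression with diagnostics.

    Fits logit P(y=1) = intercept + beta * x by iteratively reweighted least
    squares. Complete separation (the predictor ranges of the two outcome
    classes are disjoint) is detected up front and reported instead of a
    divergent fit; a degenerate (constant) predictor likewise. Reports the
    Wald 95% CI and p for the odds ratio exp(beta) and a Hosmer-Lemeshow
    goodness-of-fit test over 10 risk-decile groups.
    """
    y = _as_binary_array(outcome, "outcome").astype(float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and predictor must be equal-length 1-D sequences")
    if not np.isfinite(x).all():
        raise ValueError("predictor must be finite")
    n = len(y)
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        return LogisticFit(*([None] * 10), n=n, converged=False, separation=True,
                           message="degenerate: predictor is constant")
    x1, x0 = x[y == 1], x[y == 0]
    if x1.min() > x0.max() or x0.min() > x1.max():
        direction = "+inf" if x1.min() > x0.max() else "-inf"
        return LogisticFit(*([None] * 10), n=n, converged=False, separation=True,
                           message=f"complete separation: ML slope diverges to {direction}")

    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=max_iter)
    except Exception as exc:  # statsmodels raises on perfect separation
        return LogisticFit(*([None] * 10), n=n, converged=False, separation=True,
                           message=f"fit failed: {exc}")
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations; trace: {fit.mle_retvals}"
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not math.isfinite(se) or abs(beta) > 50:
        return LogisticFit(*([None] * 10), n=n, converged=False, separation=True,
                           message="quasi-separation: slope/SE diverged")
    z = sps.norm.ppf(0.975)
    gof_stat, gof_df, gof_p = _hosmer_lemeshow(y.astype(int), fit.predict(X))
    return LogisticFit(
        intercept=float(fit.params[0]),
        beta=beta,
        beta_se=se,
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        wald_p=float(fit.pvalues[1]),
        gof_statistic=gof_stat,
        gof_df=gof_df,
        gof_p=gof_p,
        n=n,
        converged=True,
        separation=False,
    )
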