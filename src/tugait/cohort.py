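"""Cohort-level statistics: feature screening, fusion and ROC analysis.

Features are screened one at a time with a two-sided Mann-Whitney U test
(no distributional assumption is justified at n = 18 + 18).  Significant
features are fused by the normalised average: min-max scale each to
[0, 1] over the cohort, then average per subject ("early fusion").  The
fused score is evaluated by ROC analysis with faller as the positive
class: AUC (trapezoidal), an equal-error-rate operating point (threshold
where sensitivity and specificity cross), the f1-score there, a
probability cut-off from a univariate logistic map of the raw score, and
a stratified-bootstrap percentile confidence interval for the AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError
from .io import CohortTable, Group

DEFAULT_ALPHA = 0.05
DEFAULT_N_BOOT = 2000


@dataclass
class UTestResult:
    feature: str
    mu_pos: float  # faller mean
    sd_pos: float
    mu_neg: float  # non-faller mean
    sd_neg: float
    n_pos: int
    n_neg: int
    u_statistic: float
    p_value: float
    q_value: float  # Benjamini-Hochberg, reported for transparency only
    significant: bool
    method: str  # "exact" or "asymptotic"


@dataclass
class FusedVariable:
    """Normalised-average fusion of several features.

    Stores the per-feature min/max actually used, so the same scaling can
    be re-applied to new subjects.
    """

    values: pd.Series  # per-subject fused score in [0, 1], indexed by subject_id
    features: tuple[str, ...]
    mins: dict[str, float] = field(repr=False)
    maxs: dict[str, float] = field(repr=False)
    excluded: tuple[str, ...] = ()


@dataclass
class RocResult:
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    auc: float
    auc_raw: float  # before any orientation flip
    ci_low: float
    ci_high: float
    sens: float
    spec: float
    f1: float
    prob_cutoff: float
    value_cutoff: float
    flipped: bool
    degenerate: bool
    positive_class: str = Group.FALLER.value
    n_pos: int = 0
    n_neg: int = 0


def _exact_feasible(pos: np.ndarray, neg: np.ndarray) -> bool:
    pooled = np.concatenate([pos, neg])
    no_ties = len(np.unique(pooled)) == len(pooled)
    return len(pos) <= 20 and len(neg) <= 20 and no_ties


def utest_screen(table: CohortTable, alpha: float = DEFAULT_ALPHA) -> list[UTestResult]:
    """Two-sided Mann-Whitney U test per feature, sorted by p-value.

    Uses the exact U distribution when both groups have <= 20 subjects and
    the pooled values are tie-free, otherwise the tie-corrected normal
    approximation.  A Benjamini-Hochberg q-value is attached for
    transparency but significance is flagged at the raw ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    results = []
    for feat in table.feature_names:
        pos, neg = table.group_values(feat)
        if len(pos) < 2 or len(neg) < 2:
            raise ValidationError(
                "Mann-Whitney screening needs >= 2 subjects in each group "
                f"(got {len(pos)} fallers, {len(neg)} non-fallers)"
            )
        method = "exact" if _exact_feasible(pos, neg) else "asymptotic"
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
        results.append(
            UTestResult(
                feature=feat,
                mu_pos=float(pos.mean()),
                sd_pos=float(pos.std(ddof=1)),
                mu_neg=float(neg.mean()),
                sd_neg=float(neg.std(ddof=1)),
                n_pos=len(pos),
                n_neg=len(neg),
                u_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                q_value=np.nan,
                significant=bool(res.pvalue <= alpha),
                method=method,
            )
        )
    qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return sorted(results, key=lambda r: r.p_value)


def fuse_average(table: CohortTable, features: list[str]) -> FusedVariable:
    """Min-max normalise each feature over the cohort, then average.

    Features with zero range across the cohort carry no ordering
    information; they are dropped with a warning.  The result is invariant
    to any positive affine transform of a component feature.
    """
    if len(features) < 1:
        raise ParameterError("fuse_average needs at least one feature")
    df = table.data
    scaled = {}
    mins, maxs, excluded = {}, {}, []
    for feat in features:
        if feat not in table.feature_names:
            raise ParameterError(f"unknown feature {feat!r}")
        col = df[feat].to_numpy(float)
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            warnings.warn(f"feature {feat!r} has zero range; excluded from fusion")
            excluded.append(feat)
            continue
        mins[feat], maxs[feat] = lo, hi
        scaled[feat] = (col - lo) / (hi - lo)
    if not scaled:
        raise ValidationError("all requested features have zero range")
    fused = np.mean(np.column_stack(list(scaled.values())), axis=1)
    return FusedVariable(
        values=pd.Series(fused, index=df["subject_id"].to_numpy(), name="fused"),
        features=tuple(scaled),
        mins=mins,
        maxs=maxs,
        excluded=tuple(excluded),
    )


def _labels_to_binary(labels) -> np.ndarray:
    y = np.array([Group.coerce(g).value for g in np.asarray(labels)])
    return (y == Group.FALLER.value).astype(int)


def roc_analysis(
    scores,
    labels,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    orient: str = "auto",
    fit_probability: bool = True,
) -> RocResult:
    """ROC analysis of a per-subject score against faller status.

    Parameters
    ----------
    scores, labels
        Per-subject real-valued scores and group labels; faller is the
        positive class.
    n_boot : int
        Stratified-bootstrap replicates for the 95 percent percentile AUC
        confidence interval; 0 disables the bootstrap (CI = point value).
    seed : int
        Seed for the bootstrap resampling stream.
    orient : {"auto", "fixed"}
        "auto" flips the score sign when the raw AUC is below 0.5 (and
        records the flip); "fixed" evaluates the score as given, which is
        what an unbiased permutation null requires.
    fit_probability : bool
        Fit the univariate logistic score-to-probability map (gives
        ``prob_cutoff``); disable for speed in tight simulation loops.

    The operating point is the equal-error-rate threshold: the empirical
    ROC threshold minimising |sensitivity - specificity|, ties broken
    toward the higher sensitivity.
    """
    if orient not in ("auto", "fixed"):
        raise ParameterError(f"orient must be 'auto' or 'fixed', got {orient!r}")
    scores = np.asarray(scores, dtype=float)
    y = _labels_to_binary(labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC analysis needs both classes present")

    degenerate = len(np.unique(scores)) == 1
    fpr0, tpr0, _ = roc_curve(y, scores)
    auc_raw = float(_trapezoid_auc(fpr0, tpr0))
    flipped = orient == "auto" and auc_raw < 0.5
    w = -scores if flipped else scores

    fpr, tpr, thresholds = roc_curve(y, w)
    auc_val = float(_trapezoid_auc(fpr, tpr))

    sens_curve, spec_curve = tpr, 1.0 - fpr
    gap = np.abs(sens_curve - spec_curve)
    best = np.flatnonzero(gap == gap.min())
    i = best[np.argmax(sens_curve[best])]  # tie-break: higher sensitivity
    sens, spec = float(sens_curve[i]), float(spec_curve[i])
    thr = float(thresholds[i])

    pred = w >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * precision * sens / (precision + sens) if (precision + sens) else 0.0

    value_cutoff = -thr if flipped else thr
    prob_cutoff = float("nan")
    if fit_probability and not degenerate and np.isfinite(value_cutoff):
        model = LogisticRegression(C=1e6, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(scores.reshape(-1, 1), y)
        prob_cutoff = float(model.predict_proba([[value_cutoff]])[0, 1])

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos_idx, n_pos, replace=True), rng.choice(neg_idx, n_neg, replace=True)]
            )
            bf, bt, _ = roc_curve(y[idx], w[idx])
            boots[b] = _trapezoid_auc(bf, bt)
        ci_low, ci_high = (float(q) for q in np.quantile(boots, [0.025, 0.975]))
        ci_low, ci_high = min(ci_low, auc_val), max(ci_high, auc_val)
    else:
        ci_low = ci_high = auc_val

    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=0.5 if degenerate else auc_val,
        auc_raw=auc_raw,
        ci_low=ci_low,
        ci_high=ci_high,
        sens=sens,
        spec=spec,
        f1=f1,
        prob_cutoff=prob_cutoff,
        value_cutoff=value_cutoff,
        flipped=flipped,
        degenerate=degenerate,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def utest_report(results: list[UTestResult]) -> pd.DataFrame:
    """Tabular view of screening results (one row per feature)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "mu_fallers": r.mu_pos,
                "sd_fallers": r.sd_pos,
                "mu_non_fallers": r.mu_neg,
                "sd_non_fallers": r.sd_neg,
                "U": r.u_statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "method": r.method,
            }
            for r in results
        ]
    )


def roc_report(named_results: dict[str, RocResult]) -> pd.DataFrame:
    """One row per analysed variable: AUC, TPR, 1-FPR, f1, cut-offs, CI."""
    return pd.DataFrame(
        [
            {
                "variable": name,
                "AUC": r.auc,
                "TPR": r.sens,
                "one_minus_FPR": r.spec,
                "f1_score": r.f1,
                "prob_cutoff": r.prob_cutoff,
                "value_cutoff": r.value_cutoff,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "flipped": r.flipped,
            }
            for name, r in named_results.items()
        ]
    )
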