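"""Clinical evaluation of predictor scores.

Given a continuous score per patient and the clinical table, this module
answers the questions an oncology biomarker study asks: do responders score
higher (Wilcoxon rank-sum)? how well do scores rank patients (AUC with
bootstrap CI)? where should the decision cutoff sit (Youden-index or
NPV-maximizing rules)? what are sensitivity / specificity / PPV / NPV with
Wald intervals and the responder odds ratio with a Woolf interval at that
cutoff? and do the predicted groups separate in overall survival
(Kaplan-Meier + log-rank, with long survival administratively censored)?

Throughout, a patient is *predicted responder* iff score >= threshold (ties
at the threshold predict responder); higher score = predicted sensitive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import ClinicalTable
from .predictor import ScoreVector

__all__ = [
    "CutoffSpec",
    "ConfusionMetrics",
    "SurvivalResult",
    "EvaluationReport",
    "wilcoxon_rank_sum",
    "roc_auc",
    "youden_cutoff",
    "npv_max_cutoff",
    "confusion_metrics",
    "confusion_from_counts",
    "km_logrank",
    "logistic_adjusted",
    "ppv_npv_curve",
    "evaluate_scores",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96  # normal quantile used for every 95% Wald/Woolf interval


@dataclass
class CutoffSpec:
    """A decision threshold on the score scale plus its achieved metrics."""

    threshold: float
    rule: str  # "youden" or "npv_max"
    sensitivity: float
    specificity: float
    youden_j: float
    npv: float | None


@dataclass
class ConfusionMetrics:
    """2x2 confusion counts with Wald proportion CIs and the Woolf OR CI."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    sensitivity_ci: tuple[float, float] = field(init=False)
    specificity_ci: tuple[float, float] = field(init=False)
    ppv_ci: tuple[float, float] = field(init=False)
    npv_ci: tuple[float, float] = field(init=False)
    odds_ratio: float = field(init=False)
    odds_ratio_ci: tuple[float, float] = field(init=False)
    haldane_corrected: bool = field(init=False)

    def __post_init__(self) -> None:
        self.sensitivity, self.sensitivity_ci = _wald(self.tp, self.tp + self.fn)
        self.specificity, self.specificity_ci = _wald(self.tn, self.tn + self.fp)
        self.ppv, self.ppv_ci = _wald(self.tp, self.tp + self.fp)
        self.npv, self.npv_ci = _wald(self.tn, self.tn + self.fn)
        cells = np.array([self.tp, self.fn, self.fp, self.tn], dtype=float)
        self.haldane_corrected = bool((cells == 0).any())
        if self.haldane_corrected:
            logger.warning("zero cell in 2x2 table; Haldane 0.5 correction applied to the OR")
            cells = cells + 0.5
        tp, fn, fp, tn = cells
        self.odds_ratio = (tp * tn) / (fp * fn)
        se = math.sqrt(1 / tp + 1 / fn + 1 / fp + 1 / tn)
        self.odds_ratio_ci = (
            math.exp(math.log(self.odds_ratio) - Z_95 * se),
            math.exp(math.log(self.odds_ratio) + Z_95 * se),
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "ppv": self.ppv,
            "ppv_ci": list(self.ppv_ci),
            "npv": self.npv,
            "npv_ci": list(self.npv_ci),
            "odds_ratio": self.odds_ratio,
            "odds_ratio_ci": list(self.odds_ratio_ci),
            "haldane_corrected": self.haldane_corrected,
        }


@dataclass
class SurvivalResult:
    """Two-group Kaplan-Meier summary with the log-rank test."""

    curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)
    medians: dict[str, float]  # NaN if the curve never reaches 0.5
    logrank_statistic: float
    logrank_p: float
    censor_horizon: float


@dataclass
class EvaluationReport:
    """All evaluation output for one scored cohort."""

    wilcoxon_statistic: float
    wilcoxon_p: float
    auc: float
    auc_ci: tuple[float, float]
    cutoffs: dict[str, CutoffSpec]
    confusion: dict[str, ConfusionMetrics]
    survival: SurvivalResult | None = None
    logistic: pd.DataFrame | None = None


def _wald(k: int, n: int) -> tuple[float, tuple[float, float]]:
    """Proportion k/n with a 95% Wald interval truncated to [0, 1]."""
    if n == 0:
        return float("nan"), (float("nan"), float("nan"))
    p = k / n
    half = Z_95 * math.sqrt(p * (1 - p) / n)
    return p, (max(0.0, p - half), min(1.0, p + half))


def wilcoxon_rank_sum(scores_responders, scores_nonresponders) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 8 observations and there are
    no ties; otherwise the normal approximation with tie correction.
    Returns (U statistic for the responder group, two-sided p).
    """
    a = np.asarray(scores_responders, dtype=float)
    b = np.asarray(scores_nonresponders, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via Mann-Whitney U with ties counted one-half."""
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def roc_auc(
    scores: ScoreVector,
    response: ClinicalTable,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUC of score vs responder status with a percentile bootstrap CI.

    Patients are resampled with replacement; resamples that lose a class are
    discarded (they carry no AUC).
    """
    y = response.response_indicator(scores.sample_ids)
    s = scores.z
    auc = _auc_from_scores(s, y)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    n = len(y)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        boots.append(_auc_from_scores(s[idx], yb))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return float(auc), float(lo), float(hi)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique scores, plus +/- infinity."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _counts_at(scores: np.ndarray, y: np.ndarray, thr: float) -> tuple[int, int, int, int]:
    pred = scores >= thr  # ties at the threshold predict responder
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return tp, fn, fp, tn


def youden_cutoff(scores: ScoreVector, response: ClinicalTable) -> CutoffSpec:
    """Threshold maximizing the Youden index J = sensitivity + specificity - 1.

    Ties in J are broken toward higher sensitivity, then lower threshold.
    """
    y = response.response_indicator(scores.sample_ids)
    if y.min() == y.max():
        raise ValueError("both response classes must be present")
    s = scores.z
    best = None
    for thr in _candidate_thresholds(s):
        tp, fn, fp, tn = _counts_at(s, y, thr)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            npv = tn / (tn + fn) if (tn + fn) > 0 else None
            best = (key, CutoffSpec(float(thr), "youden", sens, spec, j, npv))
    return best[1]


def npv_max_cutoff(
    scores: ScoreVector,
    response: ClinicalTable,
    min_predicted_negatives: int = 3,
) -> CutoffSpec:
    """Threshold maximizing NPV, the clinically protective cutoff rule.

    A mathematically balanced (Youden) cutoff still mislabels a material
    share of true responders; for a screening rule one instead wants
    predicted non-responders to be reliably non-responding. Maximize NPV
    over the same candidate grid, requiring at least
    ``min_predicted_negatives`` predicted non-responders so a one-patient
    tail cannot claim a vacuous NPV of 1. Ties break toward higher
    sensitivity, then lower threshold.
    """
    y = response.response_indicator(scores.sample_ids)
    if y.min() == y.max():
        raise ValueError("both response classes must be present")
    s = scores.z
    best = None
    for thr in _candidate_thresholds(s):
        tp, fn, fp, tn = _counts_at(s, y, thr)
        if (tn + fn) < min_predicted_negatives:
            continue
        npv = tn / (tn + fn)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (npv, sens, -thr)
        if best is None or key > best[0]:
            best = (key, CutoffSpec(float(thr), "npv_max", sens, spec, sens + spec - 1.0, npv))
    if best is None:
        raise ValueError(
            f"no threshold leaves >= {min_predicted_negatives} predicted non-responders"
        )
    return best[1]


def confusion_from_counts(tp: int, fn: int, fp: int, tn: int) -> ConfusionMetrics:
    """Confusion metrics straight from 2x2 counts (e.g. a published table)."""
    return ConfusionMetrics(tp=tp, fn=fn, fp=fp, tn=tn)


def confusion_metrics(
    scores: ScoreVector, response: ClinicalTable, cutoff: CutoffSpec
) -> ConfusionMetrics:
    """Confusion metrics of the score-threshold rule on a cohort."""
    y = response.response_indicator(scores.sample_ids)
    tp, fn, fp, tn = _counts_at(scores.z, y, cutoff.threshold)
    return ConfusionMetrics(tp=tp, fn=fn, fp=fp, tn=tn)


def km_logrank(
    clinical: ClinicalTable,
    predicted_groups: pd.Series,
    censor_horizon_months: float = 60.0,
) -> SurvivalResult:
    """Kaplan-Meier curves and log-rank test between two predicted groups.

    Survival beyond the horizon is censored at the horizon: deaths long
    after chemotherapy say little about chemotherapeutic response and a few
    outlying survivors otherwise dominate the tail.
    """
    groups = predicted_groups.dropna()
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 predicted groups, got {names}")
    data = clinical.data.loc[groups.index]
    time = data["os_months"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=bool)
    over = time > censor_horizon_months
    time = np.where(over, censor_horizon_months, time)
    event = np.where(over, False, event)

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    masks = {}
    for name in names:
        m = (groups == name).to_numpy()
        masks[name] = m
        if m.sum() == 0:
            raise ValueError(f"group {name!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event[m], label=str(name))
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        curves[name] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": at_risk.to_numpy(dtype=float),
            }
        )
        medians[name] = float(kmf.median_survival_time_)

    res = logrank_test(
        time[masks[names[0]]],
        time[masks[names[1]]],
        event_observed_A=event[masks[names[0]]],
        event_observed_B=event[masks[names[1]]],
    )
    return SurvivalResult(
        curves=curves,
        medians=medians,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        censor_horizon=float(censor_horizon_months),
    )


def logistic_adjusted(
    response: ClinicalTable,
    score: ScoreVector,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Multivariate logistic regression of response on score + covariates.

    Categorical covariates are reference-coded; the fit is Newton-type IRLS
    (tolerance 1e-8, at most 100 iterations). Perfect separation or
    non-convergence raises. Returns a coefficient table with Wald z and p.
    """
    import statsmodels.api as sm

    ids = list(score.sample_ids)
    y = response.response_indicator(ids)
    X = pd.DataFrame({"score": score.z}, index=ids)
    for cov in covariates or []:
        col = response.data.loc[ids, cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.astype(float)
    X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, X.to_numpy(dtype=float))
    try:
        res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=False)
    except Exception as exc:  # PerfectSeparationError and friends
        raise ValueError(f"logistic regression failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic regression did not converge in 100 iterations")
    return pd.DataFrame(
        {
            "term": list(X.columns),
            "coefficient": res.params,
            "std_err": res.bse,
            "wald_z": res.tvalues,
            "p_value": res.pvalues,
        }
    ).reset_index(drop=True)


def ppv_npv_curve(scores: ScoreVector, response: ClinicalTable) -> pd.DataFrame:
    """PPV and NPV at every candidate threshold (for cutoff-choice curves)."""
    y = response.response_indicator(scores.sample_ids)
    rows = []
    for thr in _candidate_thresholds(scores.z):
        tp, fn, fp, tn = _counts_at(scores.z, y, thr)
        rows.append(
            {
                "threshold": thr,
                "ppv": tp / (tp + fp) if tp + fp else np.nan,
                "npv": tn / (tn + fn) if tn + fn else np.nan,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
            }
        )
    return pd.DataFrame(rows)


def evaluate_scores(
    scores: ScoreVector,
    clinical: ClinicalTable,
    cutoff: CutoffSpec | None = None,
    cutoff_rule: str = "npv_max",
    censor_horizon_months: float = 60.0,
    n_boot: int = 2000,
    seed: int = 0,
    covariates: list[str] | None = None,
    min_predicted_negatives: int = 3,
) -> EvaluationReport:
    """Full evaluation of one score vector against one clinical table.

    If ``cutoff`` is given (e.g. derived on a different cohort, the way a
    locked-down predictor is validated) it is applied as-is; otherwise it is
    derived on this cohort with ``cutoff_rule``.
    """
    ids = scores.sample_ids
    y = clinical.response_indicator(ids)
    stat, p = wilcoxon_rank_sum(scores.z[y == 1], scores.z[y == 0])
    auc, lo, hi = roc_auc(scores, clinical, n_boot=n_boot, seed=seed)

    cutoffs: dict[str, CutoffSpec] = {}
    if cutoff is not None:
        cutoffs[cutoff.rule] = cutoff
    else:
        if cutoff_rule in ("youden", "both"):
            cutoffs["youden"] = youden_cutoff(scores, clinical)
        if cutoff_rule in ("npv_max", "both"):
            cutoffs["npv_max"] = npv_max_cutoff(
                scores, clinical, min_predicted_negatives=min_predicted_negatives
            )
    confusion = {
        rule: confusion_metrics(scores, clinical, spec) for rule, spec in cutoffs.items()
    }

    survival = None
    rule = next(iter(cutoffs), None)
    if rule is not None and "os_months" in clinical.data.columns:
        pred = pd.Series(
            np.where(scores.z >= cutoffs[rule].threshold, "pred_responder", "pred_non_responder"),
            index=ids,
        )
        if pred.nunique() == 2:
            survival = km_logrank(clinical, pred, censor_horizon_months)

    logistic = None
    if covariates:
        try:
            logistic = logistic_adjusted(clinical, scores, covariates)
        except ValueError as exc:
            logger.warning("adjusted logistic model skipped: %s", exc)

    return EvaluationReport(
        wilcoxon_statistic=stat,
        wilcoxon_p=p,
        auc=auc,
        auc_ci=(lo, hi),
        cutoffs=cutoffs,
        confusion=confusion,
        survival=survival,
        logistic=logistic,
    )
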