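"""Initial chemosensitivity biomarker discovery and filtering.

The discovery chain mirrors how cell-line-derived drug predictors are built:
label the most and least sensitive lines from continuous drug activity,
score every gene by a Welch two-sample t between the extreme classes, then
thin the candidate list with two filters — keep only genes measurable in
FFPE material, and only genes whose direction of differential expression
replicates in an independent treated patient cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    BiomarkerSet,
    ClinicalTable,
    DrugActivityProfile,
    ExpressionMatrix,
    RESISTANT,
    SENSITIVE,
    SensitivityLabels,
)

__all__ = [
    "select_extreme_lines",
    "rank_chemosensitivity_genes",
    "filter_ffpe_robust",
    "filter_direction_consistent",
    "welch_t",
]

logger = logging.getLogger(__name__)

# operating range recommended for extreme-line selection; values outside are
# allowed (asymmetric designs can need a slightly larger tail) but flagged
RECOMMENDED_TAIL_RANGE = (0.10, 0.35)


def _tail_fractions(tail_fraction) -> tuple[float, float]:
    if np.isscalar(tail_fraction):
        sens = resist = float(tail_fraction)
    else:
        sens, resist = (float(f) for f in tail_fraction)
    for f in (sens, resist):
        if not 0.0 < f <= 0.5:
            raise ValueError(f"tail fraction {f} outside (0, 0.5]")
        lo, hi = RECOMMENDED_TAIL_RANGE
        if not lo <= f <= hi:
            logger.warning("tail fraction %.3f outside the recommended %.2f-%.2f range", f, lo, hi)
    return sens, resist


def select_extreme_lines(
    activity: DrugActivityProfile, tail_fraction=0.30
) -> SensitivityLabels:
    """Label the most/least sensitive cell lines from continuous activity.

    The top ``ceil(f_sens * n)`` lines by activity are labeled sensitive and
    the bottom ``ceil(f_resist * n)`` resistant; the middle is excluded.
    ``tail_fraction`` may be a scalar or a ``(sensitive, resistant)`` pair.
    Ties at a tail boundary pull every tied line into the tail, so tail sizes
    can exceed their nominal counts. Only the ranks of the activity values
    matter, so any monotone rescaling of activity yields identical labels.
    """
    f_sens, f_resist = _tail_fractions(tail_fraction)
    act = activity.activity
    n = len(act)
    n_sens = int(np.ceil(f_sens * n))
    n_resist = int(np.ceil(f_resist * n))
    if n_sens < 2 or n_resist < 2:
        raise ValueError("each tail must contain at least 2 cell lines")
    if n_sens + n_resist > n:
        raise ValueError(
            f"tails overlap: {n_sens} sensitive + {n_resist} resistant > {n} lines"
        )

    values = act.to_numpy(dtype=float)
    order = np.argsort(values, kind="stable")
    sens_threshold = values[order[n - n_sens]]
    resist_threshold = values[order[n_resist - 1]]
    if sens_threshold <= resist_threshold:
        raise ValueError("tails overlap after tie expansion; reduce tail fractions")

    labels = {}
    for cid, v in act.items():
        if v >= sens_threshold:
            labels[cid] = SENSITIVE
        elif v <= resist_threshold:
            labels[cid] = RESISTANT
    return SensitivityLabels(pd.Series(labels, dtype=object))


def welch_statistic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic (a minus b); degenerate rows give 0."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    diff = a.mean(axis=1) - b.mean(axis=1)
    t = np.zeros_like(diff)
    ok = denom > 0
    t[ok] = diff[ok] / denom[ok]
    return t


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch two-sample t (a minus b) with two-sided p-values.

    Degenerate rows (zero variance in both groups and equal means) get
    statistic 0 and p 1. Equivalent to scipy's unequal-variance t-test with
    the Welch-Satterthwaite degrees of freedom, vectorized over genes.
    """
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    denom2 = va + vb
    diff = a.mean(axis=1) - b.mean(axis=1)
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = denom2 > 0
    t[ok] = diff[ok] / np.sqrt(denom2[ok])
    df = np.empty_like(diff)
    df[ok] = denom2[ok] ** 2 / (
        va[ok] ** 2 / (na - 1) + vb[ok] ** 2 / (nb - 1)
    )
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    zero_denom_diff = (~ok) & (diff != 0)
    if zero_denom_diff.any():  # identical constants per class but shifted
        t[zero_denom_diff] = np.sign(diff[zero_denom_diff]) * np.inf
        p[zero_denom_diff] = 0.0
    return t, p


def rank_chemosensitivity_genes(
    expr: ExpressionMatrix,
    labels: SensitivityLabels,
    alpha: float = 0.05,
    max_genes: int | None = 500,
) -> pd.DataFrame:
    """Score genes by Welch t between sensitive and resistant lines.

    Returns a gene-score table (columns ``gene_id``, ``statistic``,
    ``p_value``, ``direction``) restricted to ``p < alpha``, truncated to the
    ``max_genes`` largest |t|, ordered by |t| descending. ``direction`` is
    the sign of (mean sensitive - mean resistant).
    """
    labels.require_both_classes()
    sens_ids, resist_ids = labels.sensitive_ids, labels.resistant_ids
    if len(sens_ids) < 2 or len(resist_ids) < 2:
        raise ValueError("need >= 2 samples per class for a variance estimate")
    a = expr.subset_samples(sens_ids).values.to_numpy(dtype=float)
    b = expr.subset_samples(resist_ids).values.to_numpy(dtype=float)
    t, p = welch_t(a, b)
    direction = np.sign(t).astype(int)

    table = pd.DataFrame(
        {"gene_id": expr.gene_ids, "statistic": t, "p_value": p, "direction": direction}
    )
    table = table[table["p_value"] < alpha]
    table = table.reindex(
        table["statistic"].abs().sort_values(ascending=False, kind="stable").index
    )
    if max_genes is not None:
        table = table.head(int(max_genes))
    return table.reset_index(drop=True)


def filter_ffpe_robust(genes: pd.DataFrame, robust_ids) -> pd.DataFrame:
    """Restrict a gene-score table to FFPE-robust genes, preserving order."""
    robust = set(robust_ids)
    out = genes[genes["gene_id"].isin(robust)].reset_index(drop=True)
    if len(genes) and out.empty:
        raise ValueError(
            f"no overlap between {len(genes)} candidate genes and "
            f"{len(robust)} FFPE-robust genes"
        )
    logger.info("FFPE-robust filter: %d -> %d genes", len(genes), len(out))
    return out


def filter_direction_consistent(
    genes: pd.DataFrame,
    patient_expr: ExpressionMatrix,
    patient_response: ClinicalTable,
) -> pd.DataFrame:
    """Keep genes whose differential-expression direction replicates in patients.

    For each candidate gene, the sign of (mean responder - mean
    non-responder) in the patient cohort must match the cell-line direction.
    Genes absent from the patient matrix are dropped (counted in a warning);
    a zero patient-cohort difference counts as inconsistent.
    """
    resp_ids = patient_response.responder_ids
    nonresp_ids = patient_response.non_responder_ids
    if not resp_ids or not nonresp_ids:
        raise ValueError("patient cohort must contain both responders and non-responders")
    resp_ids = [s for s in resp_ids if s in patient_expr.values.columns]
    nonresp_ids = [s for s in nonresp_ids if s in patient_expr.values.columns]

    present_mask = genes["gene_id"].isin(patient_expr.values.index)
    n_missing = int((~present_mask).sum())
    if n_missing:
        logger.warning("%d candidate genes absent from patient matrix; dropped", n_missing)
    present = genes[present_mask]
    if present.empty:
        return present.reset_index(drop=True)

    sub = patient_expr.values.loc[present["gene_id"]]
    diff = sub[resp_ids].mean(axis=1) - sub[nonresp_ids].mean(axis=1)
    patient_sign = np.sign(diff.to_numpy())
    keep = patient_sign == present["direction"].to_numpy()
    out = present[keep].reset_index(drop=True)
    logger.info("direction-consistency filter: %d -> %d genes", len(genes), len(out))
    return out


def build_biomarker_set(
    drug_name: str,
    scores: pd.DataFrame,
    robust_ids=None,
    patient_expr: ExpressionMatrix | None = None,
    patient_response: ClinicalTable | None = None,
) -> tuple[BiomarkerSet, pd.DataFrame]:
    """Run the filter chain and record provenance counts at each step."""
    current = scores
    bm = BiomarkerSet(drug_name, list(current["gene_id"]), [("initial_ranking", len(scores), len(scores))])
    if robust_ids is not None:
        current = filter_ffpe_robust(current, robust_ids)
        bm = bm.with_filter("ffpe_robust", list(current["gene_id"]))
    if patient_expr is not None and patient_response is not None:
        current = filter_direction_consistent(current, patient_expr, patient_response)
        bm = bm.with_filter("direction_consistent", list(current["gene_id"]))
    return bm, current
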