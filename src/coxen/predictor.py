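"""Diagonal linear discriminant predictors with nested cross-validation.

Cell-line panels have far fewer samples (18-60 lines) than candidate genes,
so a full pooled covariance is singular; the discriminant therefore assumes
a diagonal covariance (gene independence given class). For a sample x the
raw score is

    d(x) = sum_g (mu_s,g - mu_r,g) * (x_g - (mu_s,g + mu_r,g) / 2) / var_g
           + log(pi_s / pi_r)

with class means mu, pooled per-gene variance var and class priors pi;
higher score = predicted sensitive. Feature-count selection and performance
estimation use nested leave-one-out cross-validation: the inner loop (within
each outer training fold) re-ranks genes by |Welch t| and picks the
candidate feature count k with the best inner accuracy (smallest k on ties),
so no selection information leaks into the outer performance estimate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker_discovery import welch_statistic
from .containers import ExpressionMatrix, RESISTANT, SENSITIVE, SensitivityLabels

__all__ = [
    "PredictorModel",
    "ScoreVector",
    "fit_dlda",
    "double_cross_validate",
    "score_cohort",
    "combine_scores",
]

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATE_KS = (5, 10, 20, 50, 100)


@dataclass
class PredictorModel:
    """Per-drug diagonal-LDA model producing continuous sensitivity scores."""

    drug_name: str
    gene_ids: list[str]
    mean_sensitive: np.ndarray
    mean_resistant: np.ndarray
    pooled_variance: np.ndarray
    prior_sensitive: float
    prior_resistant: float
    chosen_feature_count: int | None = None
    cv_accuracy: float | None = None

    def __post_init__(self) -> None:
        self.mean_sensitive = np.asarray(self.mean_sensitive, dtype=float)
        self.mean_resistant = np.asarray(self.mean_resistant, dtype=float)
        self.pooled_variance = np.asarray(self.pooled_variance, dtype=float)
        if (self.pooled_variance <= 0).any():
            raise ValueError("pooled variances must be strictly positive")
        if not np.isclose(self.prior_sensitive + self.prior_resistant, 1.0):
            raise ValueError("class priors must sum to 1")

    def discriminant(self, X: np.ndarray, gene_mask: np.ndarray | None = None) -> np.ndarray:
        """Raw score for samples in columns of X (genes in model order)."""
        mu_s, mu_r, var = self.mean_sensitive, self.mean_resistant, self.pooled_variance
        if gene_mask is not None:
            mu_s, mu_r, var = mu_s[gene_mask], mu_r[gene_mask], var[gene_mask]
        w = (mu_s - mu_r) / var
        mid = (mu_s + mu_r) / 2.0
        return w @ (X - mid[:, None]) + np.log(self.prior_sensitive / self.prior_resistant)

    def to_json(self, path) -> None:
        payload = {
            "drug_name": self.drug_name,
            "gene_ids": self.gene_ids,
            "mean_sensitive": self.mean_sensitive.tolist(),
            "mean_resistant": self.mean_resistant.tolist(),
            "pooled_variance": self.pooled_variance.tolist(),
            "prior_sensitive": self.prior_sensitive,
            "prior_resistant": self.prior_resistant,
            "chosen_feature_count": self.chosen_feature_count,
            "cv_accuracy": self.cv_accuracy,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PredictorModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class ScoreVector:
    """Continuous predictor output for one cohort (higher = more sensitive)."""

    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.z is None:
            self.z = standardize(self.raw)
        else:
            self.z = np.asarray(self.z, dtype=float)
        if len(self.sample_ids) != len(self.raw):
            raise ValueError("sample_ids and scores length mismatch")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "raw": self.raw, "z": self.z})


def standardize(x: np.ndarray) -> np.ndarray:
    """Within-cohort z-scores; a constant vector maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate score vector (all values equal); z set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _class_arrays(
    expr: ExpressionMatrix, labels: SensitivityLabels, gene_ids
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    gene_ids = list(gene_ids)
    sub = expr.subset_genes(gene_ids)
    a = sub.subset_samples(labels.sensitive_ids).values.to_numpy(dtype=float)
    b = sub.subset_samples(labels.resistant_ids).values.to_numpy(dtype=float)
    return a, b, gene_ids


def fit_dlda(
    expr: ExpressionMatrix,
    labels: SensitivityLabels,
    gene_ids,
    drug_name: str = "",
    equal_priors: bool = False,
) -> PredictorModel:
    """Fit a diagonal LDA on labeled cell lines over the given genes.

    Genes whose pooled variance is zero are dropped with a warning. Priors
    default to the empirical class frequencies; ``equal_priors=True`` sets
    both to 1/2 (useful when the class split is an artefact of tail
    selection rather than a prevalence estimate).
    """
    labels.require_both_classes()
    a, b, gene_ids = _class_arrays(expr, labels, gene_ids)
    n_s, n_r = a.shape[1], b.shape[1]
    if n_s < 2 or n_r < 2:
        raise ValueError("need >= 2 samples per class")
    mu_s, mu_r = a.mean(axis=1), b.mean(axis=1)
    var = ((n_s - 1) * a.var(axis=1, ddof=1) + (n_r - 1) * b.var(axis=1, ddof=1)) / (
        n_s + n_r - 2
    )
    keep = var > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped[:5])
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        mu_s, mu_r, var = mu_s[keep], mu_r[keep], var[keep]
        if not gene_ids:
            raise ValueError("all genes have zero pooled variance")
    if equal_priors:
        pi_s = pi_r = 0.5
    else:
        pi_s, pi_r = n_s / (n_s + n_r), n_r / (n_s + n_r)
    return PredictorModel(
        drug_name=drug_name,
        gene_ids=gene_ids,
        mean_sensitive=mu_s,
        mean_resistant=mu_r,
        pooled_variance=var,
        prior_sensitive=pi_s,
        prior_resistant=pi_r,
    )


def _rank_genes_by_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of genes ordered by |Welch t| (sensitive vs resistant), desc."""
    t = welch_statistic(X[:, y == 1], X[:, y == 0])
    return np.argsort(-np.abs(t), kind="stable")


def _dlda_predict(Xt: np.ndarray, yt: np.ndarray, x: np.ndarray) -> int:
    """Train DLDA on (Xt, yt) and classify one sample; 1 = sensitive."""
    a, b = Xt[:, yt == 1], Xt[:, yt == 0]
    n_s, n_r = a.shape[1], b.shape[1]
    mu_s, mu_r = a.mean(axis=1), b.mean(axis=1)
    var = ((n_s - 1) * a.var(axis=1, ddof=1) + (n_r - 1) * b.var(axis=1, ddof=1)) / (
        n_s + n_r - 2
    )
    ok = var > 0
    if not ok.any():
        return 1 if n_s >= n_r else 0
    w = (mu_s[ok] - mu_r[ok]) / var[ok]
    mid = (mu_s[ok] + mu_r[ok]) / 2.0
    d = w @ (x[ok] - mid) + np.log(n_s / n_r)
    return int(d >= 0)


def _inner_select_k(X: np.ndarray, y: np.ndarray, candidate_ks) -> int:
    """Pick the feature count with best LOO accuracy (smallest k on ties).

    Genes are re-ranked inside every leave-one-out training fold; the same
    fold ranking serves every candidate k.
    """
    ks = sorted({int(k) for k in candidate_ks if int(k) >= 1})
    if not ks:
        raise ValueError("candidate_ks contained no usable feature count")
    n = len(y)
    correct = dict.fromkeys(ks, 0)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[:, mask], y[mask]
        if yt.min() == yt.max():
            raise ValueError("a leave-one-out fold lost a class; need >= 2 per class")
        order = _rank_genes_by_t(Xt, yt)
        for k in ks:
            sel = order[: min(k, X.shape[0])]
            pred = _dlda_predict(Xt[sel], yt, X[sel, i])
            correct[k] += int(pred == y[i])
    best_k = max(ks, key=lambda k: (correct[k], -k))
    return best_k


def double_cross_validate(
    expr: ExpressionMatrix,
    labels: SensitivityLabels,
    candidate_ks=DEFAULT_CANDIDATE_KS,
    seed: int | None = None,
    drug_name: str = "",
) -> PredictorModel:
    """Nested leave-one-out CV: unbiased accuracy + feature-count selection.

    Outer loop: each cell line is held out once; genes are re-ranked and the
    feature count re-selected (inner LOO) on the remaining lines only, so the
    outer accuracy estimate carries no selection leakage. The returned model
    is refit on all lines with the feature count the inner procedure selects
    on the full panel; ``cv_accuracy`` is the outer estimate.

    ``seed`` is accepted for interface symmetry; leave-one-out folds are
    deterministic so no randomness is consumed.
    """
    if not len(tuple(candidate_ks)):
        raise ValueError("candidate_ks must be non-empty")
    labels.require_both_classes()
    ids = labels.sample_ids
    sub = expr.subset_samples(ids)
    X = sub.values.to_numpy(dtype=float)
    y = (labels.labels.loc[ids] == SENSITIVE).to_numpy(dtype=int)
    n = len(y)
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("need >= 3 samples per class for nested leave-one-out CV")

    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[:, mask], y[mask]
        k_i = _inner_select_k(Xt, yt, candidate_ks)
        order = _rank_genes_by_t(Xt, yt)[: min(k_i, X.shape[0])]
        pred = _dlda_predict(Xt[order], yt, X[order, i])
        correct += int(pred == y[i])
    cv_accuracy = correct / n

    k_final = _inner_select_k(X, y, candidate_ks)
    order = _rank_genes_by_t(X, y)[: min(k_final, X.shape[0])]
    final_genes = [sub.gene_ids[j] for j in order]
    model = fit_dlda(expr, labels, final_genes, drug_name=drug_name)
    model.chosen_feature_count = int(min(k_final, X.shape[0]))
    model.cv_accuracy = cv_accuracy
    return model


def score_cohort(model: PredictorModel, expr: ExpressionMatrix) -> ScoreVector:
    """Apply a trained predictor to a cohort.

    Model genes missing from the cohort matrix are dropped from the
    discriminant sum (no reweighting); if fewer than half the model's genes
    are present the transfer is refused.
    """
    present = [g for g in model.gene_ids if g in expr.values.index]
    if len(present) * 2 < len(model.gene_ids):
        raise ValueError(
            f"only {len(present)}/{len(model.gene_ids)} model genes present in cohort"
        )
    if len(present) < len(model.gene_ids):
        logger.warning(
            "%d model gene(s) missing from cohort; dropped from the discriminant",
            len(model.gene_ids) - len(present),
        )
    gene_mask = np.isin(np.asarray(model.gene_ids), np.asarray(present))
    X = expr.subset_genes([g for g, m in zip(model.gene_ids, gene_mask) if m]).values.to_numpy(
        dtype=float
    )
    raw = model.discriminant(X, gene_mask)
    return ScoreVector(expr.sample_ids, raw)


def combine_scores(score_a: ScoreVector, score_b: ScoreVector) -> ScoreVector:
    """Equal-weight combination of two single-drug predictors.

    Under the drugs-act-independently assumption the combined score is
    ``(z_a + z_b) / sqrt(2)`` (unit variance if the inputs are independent
    standard normals), then re-standardized within the cohort. Symmetric in
    its arguments.
    """
    if list(score_a.sample_ids) != list(score_b.sample_ids):
        raise ValueError("combine_scores requires identical sample sets in identical order")
    raw = (score_a.z + score_b.z) / np.sqrt(2.0)
    return ScoreVector(list(score_a.sample_ids), raw)
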