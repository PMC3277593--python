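"""Correlation-of-correlations concordance ("COXEN") coefficients.

For a set of candidate genes measured both in a cell panel (set A) and a
patient cohort (set B), compute each set's gene-gene Pearson correlation
matrix and then, per gene, correlate that gene's correlation vector in A
with its vector in B (self-correlation removed). A coefficient near 1 means
the gene sits in the same co-expression neighbourhood in vitro and in vivo;
such genes are the ones worth carrying from cell lines to patients.

Significance is assessed by permutation: gene identities of set B's
correlation matrix are shuffled, breaking the A-to-B gene matching while
leaving each matrix's internal structure intact — exactly the null the
concordance claim is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BiomarkerSet, ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "CoxenCoefficients",
    "correlation_matrix",
    "coxen_coefficients",
    "coxen_permutation_test",
    "select_coxen_genes",
]


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix with gene labels."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if v.shape != (n, n):
            raise ValueError(f"correlation matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        self.values = v


@dataclass
class CoxenCoefficients:
    """Per-gene concordance coefficients with optional permutation p-values."""

    gene_ids: list[str]
    coefficient: np.ndarray
    p_value: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.gene_ids, "coefficient": self.coefficient})
        if self.p_value is not None:
            out["p_value"] = self.p_value
        return out


def correlation_matrix(expr: ExpressionMatrix, gene_ids) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the listed genes across samples."""
    gene_ids = list(gene_ids)
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    sub = expr.subset_genes(gene_ids).values.to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise ValueError(f"zero-variance gene(s): {[gene_ids[i] for i in zero_var[:5]]}")
    corr = np.corrcoef(sub)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(gene_ids, corr)


def _rowwise_corr_offdiag(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two square matrices, with the
    diagonal entry excluded from each row. Constant rows yield 0."""
    n = a.shape[0]
    if n < 3:
        raise ValueError("need >= 3 genes so each off-diagonal row has >= 2 entries")
    mask = ~np.eye(n, dtype=bool)
    av = a[mask].reshape(n, n - 1)
    bv = b[mask].reshape(n, n - 1)
    av = av - av.mean(axis=1, keepdims=True)
    bv = bv - bv.mean(axis=1, keepdims=True)
    num = (av * bv).sum(axis=1)
    den = np.sqrt((av**2).sum(axis=1) * (bv**2).sum(axis=1))
    out = np.zeros(n)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def coxen_coefficients(corr_a: CorrelationMatrix, corr_b: CorrelationMatrix) -> CoxenCoefficients:
    """Per-gene correlation between the two correlation matrices' rows.

    Both matrices must carry the same genes in the same order. For gene g the
    coefficient is the Pearson correlation of row g of A with row g of B,
    each with the (g, g) entry removed. Symmetric in its two arguments.
    """
    if corr_a.gene_ids != corr_b.gene_ids:
        raise ValueError("gene sets / order differ between the two correlation matrices")
    coef = _rowwise_corr_offdiag(corr_a.values, corr_b.values)
    return CoxenCoefficients(list(corr_a.gene_ids), coef)


def coxen_permutation_test(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    gene_ids,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CoxenCoefficients:
    """Concordance coefficients with permutation p-values.

    The null redraws the gene identities of set B's correlation matrix
    (rows and columns permuted together), recomputes per-gene coefficients,
    and counts how often the |null coefficient| reaches the observed one:
    ``p = (1 + #{|null| >= |obs|}) / (n_permutations + 1)``, two-sided.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    gene_ids = list(gene_ids)
    corr_a = correlation_matrix(expr_a, gene_ids)
    corr_b = correlation_matrix(expr_b, gene_ids)
    observed = _rowwise_corr_offdiag(corr_a.values, corr_b.values)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    n = len(gene_ids)
    exceed = np.zeros(n, dtype=int)
    abs_obs = np.abs(observed)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        b_perm = corr_b.values[np.ix_(perm, perm)]
        null = _rowwise_corr_offdiag(corr_a.values, b_perm)
        exceed += np.abs(null) >= abs_obs - 1e-12
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return CoxenCoefficients(gene_ids, observed, p, n_permutations, int(seed))


def select_coxen_genes(
    coeffs: CoxenCoefficients, alpha: float, candidates: pd.DataFrame
) -> tuple[BiomarkerSet, pd.DataFrame]:
    """Keep candidate genes with significant concordance, ordered by |t|.

    Returns the surviving rows of the candidate gene-score table (its
    |statistic| ordering preserved) plus a BiomarkerSet carrying provenance.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if coeffs.p_value is None and alpha < 1.0:
        raise ValueError("coefficients carry no p-values; run coxen_permutation_test")
    in_coeffs = candidates["gene_id"].isin(set(coeffs.gene_ids))
    kept = candidates[in_coeffs]
    if alpha < 1.0:  # alpha = 1 keeps every candidate, including exact p = 1
        pmap = dict(zip(coeffs.gene_ids, coeffs.p_value))
        kept = kept[[pmap[g] < alpha for g in kept["gene_id"]]]
    kept = kept.reindex(
        kept["statistic"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    if kept.empty:
        raise ValueError(
            "no candidate gene passed the concordance filter; "
            "increase alpha or supply more candidates"
        )
    bm = BiomarkerSet(
        drug_name="",
        gene_ids=list(kept["gene_id"]),
        provenance=[("coxen_concordance", len(candidates), len(kept))],
    )
    return bm, kept
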