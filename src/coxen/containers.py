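"""Shared in-memory containers for expression, drug-activity and clinical data.

Everything downstream operates on these few types: an expression matrix
(genes x samples), a per-cell-line drug-activity profile, binary
sensitivity labels derived from the activity extremes, and a per-patient
clinical table (response class, overall survival, covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DrugActivityProfile",
    "SensitivityLabels",
    "ClinicalTable",
    "BiomarkerSet",
    "RESPONDER",
    "NON_RESPONDER",
    "SENSITIVE",
    "RESISTANT",
]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
SENSITIVE = "sensitive"
RESISTANT = "resistant"

# clinical response codes collapsed to the binary endpoint: complete
# responders vs everyone else (partial response / stable / progressive disease)
RESPONSE_CODE_MAP = {
    "CR": RESPONDER,
    "PR": NON_RESPONDER,
    "SD": NON_RESPONDER,
    "PD": NON_RESPONDER,
}


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix with unique IDs on both axes.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns. No missing
        values are allowed.
    platform_tag
        Free-text platform label (e.g. an array design name).
    """

    values: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.platform_tag)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.platform_tag)


@dataclass
class DrugActivityProfile:
    """Per-cell-line activity for one drug; higher value = more sensitive.

    The convention matches a -log(GI50)-like scale: growth-inhibiting
    concentration transformed so that sensitive lines score high. Percent-kill
    data fits the same convention directly.
    """

    drug_name: str
    activity: pd.Series  # index: cell-line IDs
    source_metric: str = "gi50_neg_log"  # or "percent_kill"

    def __post_init__(self) -> None:
        if self.activity.index.has_duplicates:
            raise ValueError("duplicate cell-line IDs in activity profile")
        if not np.isfinite(self.activity.to_numpy(dtype=float)).all():
            raise ValueError("activity values must be finite")
        if self.source_metric not in ("gi50_neg_log", "percent_kill"):
            raise ValueError(f"unknown source_metric: {self.source_metric!r}")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.activity.index)


@dataclass
class SensitivityLabels:
    """Binary sensitive/resistant labels for a subset of cell lines."""

    labels: pd.Series  # index: sample IDs, values in {sensitive, resistant}

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {SENSITIVE, RESISTANT}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample IDs in labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def sensitive_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == SENSITIVE])

    @property
    def resistant_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == RESISTANT])

    def require_both_classes(self) -> None:
        if not self.sensitive_ids or not self.resistant_ids:
            raise ValueError("both sensitive and resistant classes must be non-empty")


@dataclass
class ClinicalTable:
    """Per-patient clinical annotations for a scored cohort.

    Columns: ``response`` (responder / non_responder, CR vs PR/SD/PD),
    ``os_months`` (overall survival, months), ``event`` (True = death
    observed, False = censored) and optional covariates ``age``, ``stage``,
    ``debulking``, ``race``.
    """

    data: pd.DataFrame  # index: sample IDs

    REQUIRED = ("response", "os_months", "event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs in clinical table")
        bad = set(self.data["response"].dropna().unique()) - {RESPONDER, NON_RESPONDER}
        if bad:
            raise ValueError(f"unknown response values: {sorted(bad)}")
        os_months = self.data["os_months"].to_numpy(dtype=float)
        if (os_months < 0).any():
            raise ValueError("os_months must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def response(self) -> pd.Series:
        return self.data["response"]

    @property
    def responder_ids(self) -> list[str]:
        return list(self.data.index[self.data["response"] == RESPONDER])

    @property
    def non_responder_ids(self) -> list[str]:
        return list(self.data.index[self.data["response"] == NON_RESPONDER])

    def response_indicator(self, sample_ids=None) -> np.ndarray:
        """1 for responders, 0 for non-responders, ordered by sample_ids."""
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        resp = self.data.loc[ids, "response"]
        return (resp == RESPONDER).to_numpy(dtype=int)


@dataclass
class BiomarkerSet:
    """Final ordered biomarker list for one drug, with filter provenance.

    ``provenance`` records each applied filter as (name, n_before, n_after);
    counts are non-increasing along the chain.
    """

    drug_name: str
    gene_ids: list[str]
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("biomarker gene IDs must be unique")
        for name, before, after in self.provenance:
            if after > before:
                raise ValueError(f"filter {name!r} increased gene count {before}->{after}")

    def with_filter(self, name: str, gene_ids: list[str]) -> "BiomarkerSet":
        return BiomarkerSet(
            drug_name=self.drug_name,
            gene_ids=list(gene_ids),
            provenance=self.provenance + [(name, len(self.gene_ids), len(gene_ids))],
        )
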