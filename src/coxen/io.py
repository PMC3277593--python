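"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices are tab-delimited (first column gene IDs, header row
sample IDs); clinical tables, drug activity and scores are CSV; models,
truths and reports are JSON. Everything round-trips: write-then-read is the
identity up to float formatting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    DrugActivityProfile,
    ExpressionMatrix,
    RESPONSE_CODE_MAP,
)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_drug_activity",
    "write_drug_activity",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_expression_matrix(path, fmt: str = "tsv") -> ExpressionMatrix:
    """Parse a genes x samples TSV.

    Duplicate gene IDs are collapsed by keeping the row with the highest mean
    expression (the usual convention when several probes map to one gene
    symbol); the number of collapsed rows is logged. Ragged rows and
    non-numeric cells raise :class:`ParseError` naming the line.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format: {fmt!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}: duplicate sample IDs in header")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            gene_ids.append(parts[0])
    arr = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    if len(set(gene_ids)) != len(gene_ids):
        # several measurements per gene: keep the row with the highest mean,
        # preserving each gene's first-appearance order
        means = arr.mean(axis=1) if arr.size else np.empty(0)
        chosen = (
            pd.DataFrame({"gene": gene_ids, "mean": means, "pos": range(len(gene_ids))})
            .sort_values(["gene", "mean"], kind="stable")
            .drop_duplicates("gene", keep="last")
            .sort_values("pos")
        )
        logger.warning(
            "%s: collapsed %d duplicate gene row(s) by max mean expression",
            path,
            len(gene_ids) - len(chosen),
        )
        arr = arr[chosen["pos"].to_numpy()]
        gene_ids = list(chosen["gene"])
    return ExpressionMatrix(pd.DataFrame(arr, index=gene_ids, columns=sample_ids, dtype=float))


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical_table(path) -> ClinicalTable:
    """Parse a clinical CSV with columns sample_id, response, os_months, event
    and optional covariates (age, stage, debulking, race).

    Response codes CR / PR / SD / PD collapse to responder vs non_responder.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    codes = df["response"].astype(str).str.upper()
    unknown = sorted(set(codes.unique()) - set(RESPONSE_CODE_MAP))
    if unknown:
        raise ParseError(f"{path}: unknown response code(s): {unknown}")
    df["response"] = codes.map(RESPONSE_CODE_MAP)
    if (df["os_months"].astype(float) < 0).any():
        bad = df.index[df["os_months"].astype(float) < 0][0]
        raise ParseError(f"{path}: negative os_months for sample {bad!r}")
    ev = df["event"].astype(str).str.lower()
    bad_ev = sorted(set(ev.unique()) - {"death", "censored", "true", "false", "1", "0"})
    if bad_ev:
        raise ParseError(f"{path}: unknown event code(s): {bad_ev}")
    df["event"] = ev.isin({"death", "true", "1"})
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    out = clinical.data.copy()
    out["response"] = np.where(out["response"] == "responder", "CR", "PD")
    out["event"] = np.where(out["event"], "death", "censored")
    out.to_csv(path, index_label="sample_id")


def read_drug_activity(path) -> DrugActivityProfile:
    """Parse a CSV with columns cell_line_id, activity and optional
    drug_name / source_metric columns (constant per file)."""
    df = pd.read_csv(path, dtype={"cell_line_id": str})
    if "cell_line_id" not in df.columns or "activity" not in df.columns:
        raise ParseError(f"{path}: need cell_line_id and activity columns")
    drug = str(df["drug_name"].iloc[0]) if "drug_name" in df.columns else "drug"
    metric = (
        str(df["source_metric"].iloc[0]) if "source_metric" in df.columns else "gi50_neg_log"
    )
    return DrugActivityProfile(
        drug, pd.Series(df["activity"].to_numpy(dtype=float), index=df["cell_line_id"]), metric
    )


def write_drug_activity(profile: DrugActivityProfile, path) -> None:
    pd.DataFrame(
        {
            "cell_line_id": profile.cell_line_ids,
            "activity": profile.activity.to_numpy(),
            "drug_name": profile.drug_name,
            "source_metric": profile.source_metric,
        }
    ).to_csv(path, index=False)
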