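"""End-to-end orchestration: discovery -> filters -> concordance -> training
-> scoring -> clinical evaluation, for two drugs plus their combination.

The simulated study mirrors the real design: each drug gets its own cell
panel (its own informative genes and activity data), a shared *training*
patient cohort supplies the direction-consistency and concordance filters,
an independent frozen-tissue *test* cohort provides cutoff derivation and
evaluation, and an FFPE-degraded *validation* cohort tests prospective
transfer of the locked-down predictors and cutoffs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import biomarker_discovery as disc
from . import coxen_core
from . import evaluation as ev
from . import predictor as pred
from .containers import BiomarkerSet, ClinicalTable, ExpressionMatrix
from .synthetic_data import SimulationConfig, SyntheticTruth, simulate_cell_panel, \
    simulate_ffpe_pair, simulate_patient_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


def derive_seed(master: int, tag: str) -> int:
    """Deterministic 31-bit sub-seed for one named pipeline stage."""
    h = np.random.SeedSequence([int(master), abs(hash_tag(tag))]).generate_state(1)[0]
    return int(h % (2**31))


def hash_tag(tag: str) -> int:
    # stable across processes (builtin hash of str is salted)
    return sum((i + 1) * ord(c) for i, c in enumerate(tag)) % (2**31)


@dataclass
class PipelineConfig:
    """Every knob of the two-drug simulated study, serializable to YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tail_fraction: float | tuple[float, float] = 0.30
    discovery_alpha: float = 0.05
    max_genes: int = 500
    coxen_alpha: float = 0.05
    n_permutations: int = 1000
    candidate_ks: tuple[int, ...] = pred.DEFAULT_CANDIDATE_KS
    cutoff_rule: str = "npv_max"
    min_predicted_negatives: int = 3
    censor_horizon_months: float = 60.0
    n_boot: int = 2000
    include_ffpe_cohort: bool = True
    covariates: tuple[str, ...] = ()
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["simulation"] = dataclasses.asdict(self.simulation)
        payload["tail_fraction"] = (
            list(self.tail_fraction) if not np.isscalar(self.tail_fraction) else self.tail_fraction
        )
        payload["candidate_ks"] = list(self.candidate_ks)
        payload["covariates"] = list(self.covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["simulation"] = SimulationConfig(**payload.get("simulation", {}))
        if isinstance(payload.get("tail_fraction"), list):
            payload["tail_fraction"] = tuple(payload["tail_fraction"])
        payload["candidate_ks"] = tuple(payload.get("candidate_ks", pred.DEFAULT_CANDIDATE_KS))
        payload["covariates"] = tuple(payload.get("covariates", ()))
        return cls(**payload)


@dataclass
class DrugResult:
    """Artifacts for one drug's predictor."""

    drug_name: str
    biomarkers: BiomarkerSet
    model: pred.PredictorModel
    scores_test: pred.ScoreVector
    scores_ffpe: pred.ScoreVector | None
    report_test: ev.EvaluationReport
    report_ffpe: ev.EvaluationReport | None


@dataclass
class PipelineResult:
    """Consolidated output of one pipeline run."""

    config: PipelineConfig
    truth: SyntheticTruth
    drugs: dict[str, DrugResult]
    combination_scores_test: pred.ScoreVector
    combination_scores_ffpe: pred.ScoreVector | None
    combination_report_test: ev.EvaluationReport
    combination_report_ffpe: ev.EvaluationReport | None
    test_clinical: ClinicalTable
    ffpe_clinical: ClinicalTable | None

    def report_dict(self) -> dict:
        def _cutoffs(report: ev.EvaluationReport) -> dict:
            return {
                rule: {
                    "threshold": spec.threshold,
                    "sensitivity": spec.sensitivity,
                    "specificity": spec.specificity,
                    "youden_j": spec.youden_j,
                    "npv": spec.npv,
                }
                for rule, spec in report.cutoffs.items()
            }

        def _report(report: ev.EvaluationReport | None) -> dict | None:
            if report is None:
                return None
            out = {
                "wilcoxon_p": report.wilcoxon_p,
                "auc": report.auc,
                "auc_ci": list(report.auc_ci),
                "cutoffs": _cutoffs(report),
                "confusion": {r: m.as_dict() for r, m in report.confusion.items()},
            }
            if report.survival is not None:
                out["survival"] = {
                    "medians": report.survival.medians,
                    "logrank_p": report.survival.logrank_p,
                    "censor_horizon": report.survival.censor_horizon,
                }
            if report.logistic is not None:
                out["logistic"] = report.logistic.to_dict(orient="records")
            return out

        payload = {
            "config": {
                **dataclasses.asdict(self.config),
                "simulation": dataclasses.asdict(self.config.simulation),
            },
            "drugs": {},
            "combination": {
                "test": _report(self.combination_report_test),
                "ffpe": _report(self.combination_report_ffpe),
            },
        }
        for name, dr in self.drugs.items():
            payload["drugs"][name] = {
                "biomarkers": dr.biomarkers.gene_ids,
                "filter_provenance": [list(p) for p in dr.biomarkers.provenance],
                "chosen_feature_count": dr.model.chosen_feature_count,
                "cv_accuracy": dr.model.cv_accuracy,
                "test": _report(dr.report_test),
                "ffpe": _report(dr.report_ffpe),
            }
        return payload

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report_dict(), fh, indent=1, sort_keys=True, default=float)


def _build_biomarkers(
    drug_name: str,
    panel: ExpressionMatrix,
    labels,
    train_expr: ExpressionMatrix,
    train_clinical: ClinicalTable,
    robust_ids,
    config: PipelineConfig,
) -> tuple[BiomarkerSet, pd.DataFrame]:
    scores = disc.rank_chemosensitivity_genes(
        panel, labels, alpha=config.discovery_alpha, max_genes=config.max_genes
    )
    if scores.empty:
        raise RuntimeError(f"[{drug_name}] no genes pass the initial |t| screen")
    bm, current = disc.build_biomarker_set(
        drug_name,
        scores,
        robust_ids=robust_ids,
        patient_expr=train_expr,
        patient_response=train_clinical,
    )
    if current.empty:
        raise RuntimeError(f"[{drug_name}] filter chain removed every candidate gene")
    genes = list(current["gene_id"])
    if config.coxen_alpha >= 1.0 or len(genes) < 3:
        if len(genes) < 3:
            logger.warning(
                "[%s] only %d candidates; concordance filter skipped", drug_name, len(genes)
            )
        coeffs = None
        kept = current
    else:
        coeffs = coxen_core.coxen_permutation_test(
            panel,
            train_expr,
            genes,
            n_permutations=config.n_permutations,
            seed=derive_seed(config.seed, f"coxen_{drug_name}"),
        )
        _, kept = coxen_core.select_coxen_genes(coeffs, config.coxen_alpha, current)
    bm = bm.with_filter("coxen_concordance", list(kept["gene_id"]))
    return bm, kept


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full simulated two-drug study.

    Deterministic: identical config (including seed) reproduces the result
    bit-for-bit. Any stage failure raises with the stage name in the message.
    """
    sim = config.simulation
    master = config.seed

    # --- simulate the study --------------------------------------------
    panels = {}
    for drug in ("drug_A", "drug_B"):
        cfg = replace(sim, seed=derive_seed(master, f"panel_{drug}"))
        panels[drug] = simulate_cell_panel(cfg, drug_name=drug)
    truth = SyntheticTruth.merge(panels["drug_A"][2], panels["drug_B"][2])

    train_expr, train_clin, truth = simulate_patient_cohort(
        replace(sim, seed=derive_seed(master, "train_cohort")), truth, "train-cohort"
    )
    test_expr, test_clin, _ = simulate_patient_cohort(
        replace(sim, seed=derive_seed(master, "test_cohort")), truth, "test-cohort"
    )

    ffpe_expr = ffpe_clin = None
    robust_ids = None
    if config.include_ffpe_cohort:
        ffpe_cfg = replace(sim, seed=derive_seed(master, "ffpe"))
        ffpe_src, ffpe_clin, _ = simulate_patient_cohort(
            replace(sim, seed=derive_seed(master, "ffpe_cohort")), truth, "ffpe-cohort"
        )
        ffpe_expr, ffpe_truth = simulate_ffpe_pair(ffpe_src, ffpe_cfg)
        robust_ids = ffpe_truth.robust_genes
        truth = replace(truth, robust_genes=list(robust_ids))

    # --- per-drug chain ------------------------------------------------
    drugs: dict[str, DrugResult] = {}
    for drug, (panel_expr, activity, _) in panels.items():
        labels = disc.select_extreme_lines(activity, config.tail_fraction)
        bm, kept = _build_biomarkers(
            drug, panel_expr, labels, train_expr, train_clin, robust_ids, config
        )
        model = pred.double_cross_validate(
            panel_expr.subset_genes(bm.gene_ids),
            labels,
            candidate_ks=config.candidate_ks,
            drug_name=drug,
        )
        scores_test = pred.score_cohort(model, test_expr)
        report_test = ev.evaluate_scores(
            scores_test,
            test_clin,
            cutoff_rule=config.cutoff_rule,
            censor_horizon_months=config.censor_horizon_months,
            n_boot=config.n_boot,
            seed=derive_seed(master, f"eval_test_{drug}"),
            min_predicted_negatives=config.min_predicted_negatives,
        )
        scores_ffpe = report_ffpe = None
        if ffpe_expr is not None:
            scores_ffpe = pred.score_cohort(model, ffpe_expr)
            locked = next(iter(report_test.cutoffs.values()))
            report_ffpe = ev.evaluate_scores(
                scores_ffpe,
                ffpe_clin,
                cutoff=locked,
                censor_horizon_months=config.censor_horizon_months,
                n_boot=config.n_boot,
                seed=derive_seed(master, f"eval_ffpe_{drug}"),
                covariates=list(config.covariates),
            )
        drugs[drug] = DrugResult(drug, bm, model, scores_test, scores_ffpe, report_test, report_ffpe)

    # --- combination ----------------------------------------------------
    combo_test = pred.combine_scores(drugs["drug_A"].scores_test, drugs["drug_B"].scores_test)
    combo_report_test = ev.evaluate_scores(
        combo_test,
        test_clin,
        cutoff_rule=config.cutoff_rule,
        censor_horizon_months=config.censor_horizon_months,
        n_boot=config.n_boot,
        seed=derive_seed(master, "eval_test_combo"),
        min_predicted_negatives=config.min_predicted_negatives,
    )
    combo_ffpe = combo_report_ffpe = None
    if ffpe_expr is not None:
        combo_ffpe = pred.combine_scores(drugs["drug_A"].scores_ffpe, drugs["drug_B"].scores_ffpe)
        locked = next(iter(combo_report_test.cutoffs.values()))
        combo_report_ffpe = ev.evaluate_scores(
            combo_ffpe,
            ffpe_clin,
            cutoff=locked,
            censor_horizon_months=config.censor_horizon_months,
            n_boot=config.n_boot,
            seed=derive_seed(master, "eval_ffpe_combo"),
            covariates=list(config.covariates),
        )

    return PipelineResult(
        config=config,
        truth=truth,
        drugs=drugs,
        combination_scores_test=combo_test,
        combination_scores_ffpe=combo_ffpe,
        combination_report_test=combo_report_test,
        combination_report_ffpe=combo_report_ffpe,
        test_clinical=test_clin,
        ffpe_clinical=ffpe_clin,
    )
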