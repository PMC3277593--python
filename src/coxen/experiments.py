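"""Calibration and recovery experiments over many simulated studies.

Two standard experiments validate the whole pipeline:

* **Null calibration** — no planted expression effect and a survival hazard
  ratio of 1. Any honest procedure must then report chance-level accuracy
  and AUC and uniformly distributed test p-values. The significance filters
  run at alpha = 1 here (with no real signal an alpha < 1 screen correctly
  empties the candidate list, which would leave nothing to calibrate), and
  the |t| pre-screen is not truncated so the nested-CV accuracy estimate is
  free of selection leakage.
* **Signal recovery** — the default planted effect. The combination
  predictor should rank held-out synthetic patients well and the surviving
  biomarkers should be mostly the planted informative genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import PipelineConfig, run_pipeline
from .synthetic_data import SimulationConfig

__all__ = ["NullCalibration", "SignalRecovery", "null_calibration", "signal_recovery"]


@dataclass
class NullCalibration:
    """Per-run outputs of the null-calibration experiment."""

    cv_accuracies: np.ndarray  # one per drug model per run
    aucs: np.ndarray  # combination predictor, held-out cohort
    wilcoxon_p: np.ndarray
    logrank_p: np.ndarray

    @property
    def mean_cv_accuracy(self) -> float:
        return float(self.cv_accuracies.mean())

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())


@dataclass
class SignalRecovery:
    """Per-run outputs of the signal-recovery experiment."""

    aucs_test: np.ndarray  # combination predictor, frozen held-out cohort
    aucs_ffpe: np.ndarray  # combination predictor, FFPE held-out cohort
    biomarker_precisions: np.ndarray  # planted-informative fraction, per drug

    @property
    def mean_auc(self) -> float:
        return float(np.concatenate([self.aucs_test, self.aucs_ffpe]).mean())

    @property
    def mean_precision(self) -> float:
        return float(self.biomarker_precisions.mean())


def _null_config(seed: int) -> PipelineConfig:
    sim = SimulationConfig(effect_size=0.0, hazard_ratio=1.0, n_patients=100, seed=seed)
    return PipelineConfig(
        simulation=sim,
        discovery_alpha=1.0,
        max_genes=None,
        coxen_alpha=1.0,
        candidate_ks=(5, 10, 20),
        n_boot=0,
        include_ffpe_cohort=False,
        seed=seed,
    )


def null_calibration(n_runs: int = 200, seed: int = 0) -> NullCalibration:
    """Run ``n_runs`` independent null studies and collect the calibration
    quantities. Seeds are ``seed, seed+1, ...`` so runs are independent and
    the whole experiment is reproducible from one integer."""
    accs, aucs, wps, lps = [], [], [], []
    for i in range(n_runs):
        res = run_pipeline(_null_config(seed + i))
        accs.extend(dr.model.cv_accuracy for dr in res.drugs.values())
        report = res.combination_report_test
        aucs.append(report.auc)
        wps.append(report.wilcoxon_p)
        if report.survival is not None:
            lps.append(report.survival.logrank_p)
    return NullCalibration(
        np.asarray(accs), np.asarray(aucs), np.asarray(wps), np.asarray(lps)
    )


def _signal_config(seed: int) -> PipelineConfig:
    sim = SimulationConfig(n_patients=100, seed=seed)  # defaults: effect 1.5, 60 lines
    return PipelineConfig(simulation=sim, n_boot=200, n_permutations=500, seed=seed)


def signal_recovery(n_runs: int = 5, seed: int = 0) -> SignalRecovery:
    """Run ``n_runs`` studies at the default planted effect and measure the
    combination predictor's held-out AUC and the biomarker precision."""
    aucs_t, aucs_f, precs = [], [], []
    for i in range(n_runs):
        res = run_pipeline(_signal_config(seed + i))
        aucs_t.append(res.combination_report_test.auc)
        aucs_f.append(res.combination_report_ffpe.auc)
        informative = set(res.truth.informative_genes)
        for dr in res.drugs.values():
            kept = set(dr.biomarkers.gene_ids)
            precs.append(len(kept & informative) / max(len(kept), 1))
    return SignalRecovery(np.asarray(aucs_t), np.asarray(aucs_f), np.asarray(precs))
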