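"""Synthetic cell panels, patient cohorts and frozen/FFPE pairs.

The generator emulates the statistical structure the co-expression
extrapolation analysis assumes:

* a cell panel in which a subset of "informative" genes tracks a continuous
  drug-activity phenotype (higher activity = more sensitive, a
  -log(GI50)-like convention),
* patient cohorts that share gene-gene co-expression structure with the
  panel on a "concordant" gene subset — implemented with shared latent
  factors — and carry a planted responder/non-responder expression effect
  plus exponential survival times with a planted hazard ratio,
* paired frozen/FFPE profiles in which only a configurable fraction of
  genes survives FFPE degradation; non-robust genes lose their signal.

Every operation draws from its own stream seeded by (config.seed, op-id), so
identical configs reproduce outputs exactly and the three operations never
share a stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    DrugActivityProfile,
    ExpressionMatrix,
    NON_RESPONDER,
    RESPONDER,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cell_panel",
    "simulate_patient_cohort",
    "simulate_ffpe_pair",
]

# sub-stream identifiers so panel / cohort / FFPE draws are independent
_STREAM_PANEL = 0
_STREAM_COHORT = 1
_STREAM_FFPE = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    n_genes, n_cell_lines, n_patients
        Dimensions of the generated matrices.
    n_informative
        Number of genes whose expression tracks drug activity (cell panel)
        and response class (patients).
    n_concordant
        Number of genes whose co-expression structure is shared between the
        panel and patient cohorts via latent factors. Informative genes are
        drawn into the concordant set first (drug-associated genes are
        assumed co-regulated in vitro and in vivo — the premise that makes
        cell-line-to-patient extrapolation possible at all).
    effect_size
        Standardized mean shift (units of ``noise_sd``) between the classes.
    response_rate
        Fraction of cohort patients labeled responder (complete response).
    ffpe_robust_fraction
        Fraction of genes that survive FFPE degradation.
    hazard_ratio
        Planted death-hazard ratio, non-responder vs responder.
    median_survival_responder
        Responder median overall survival in months (exponential scale).
    censor_admin_months / censor_uniform_max
        Administrative censoring horizon and the upper bound of an
        independent uniform censoring time.
    n_factors, latent_loading
        Number of shared latent factors and the loading magnitude of each
        concordant gene on its (single, randomly assigned) factor.
    noise_sd
        Residual per-gene noise SD.
    """

    n_genes: int = 400
    n_cell_lines: int = 60
    n_patients: int = 55
    n_informative: int = 20
    n_concordant: int = 60
    effect_size: float = 1.5
    response_rate: float = 0.58
    ffpe_robust_fraction: float = 0.55
    hazard_ratio: float = 2.5
    median_survival_responder: float = 60.0
    censor_admin_months: float = 120.0
    censor_uniform_max: float = 240.0
    n_factors: int = 4
    latent_loading: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cell_lines <= 0 or self.n_patients <= 0:
            raise ValueError("matrix dimensions must be positive")
        if self.n_informative > self.n_genes:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_genes ({self.n_genes})"
            )
        if self.n_concordant > self.n_genes:
            raise ValueError(
                f"n_concordant ({self.n_concordant}) exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 < self.response_rate < 1.0:
            raise ValueError("response_rate must be in (0, 1)")
        if not 0.0 <= self.ffpe_robust_fraction <= 1.0:
            raise ValueError("ffpe_robust_fraction must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth annotations for recovery tests.

    ``factor_loadings`` (genes x factors, zero rows outside the concordant
    set) is carried so a patient cohort can reuse the panel's latent
    structure; it is part of the generative state, not something an analysis
    is allowed to peek at.
    """

    informative_genes: list[str] = field(default_factory=list)
    concordant_genes: list[str] = field(default_factory=list)
    robust_genes: list[str] = field(default_factory=list)
    directions: dict[str, int] = field(default_factory=dict)
    hazard_ratio: float | None = None
    factor_loadings: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in (1, -1)}
        if bad:
            raise ValueError(f"directions must be +1/-1, got {bad}")

    @classmethod
    def merge(cls, first: "SyntheticTruth", second: "SyntheticTruth") -> "SyntheticTruth":
        """Combine truths from two independently simulated panels.

        Used by the two-drug pipeline: the merged cohort shares latent
        structure with both panels. On gene collisions the first truth wins.
        """
        directions = dict(second.directions)
        directions.update(first.directions)
        loadings = None
        if first.factor_loadings is not None and second.factor_loadings is not None:
            a, b = first.factor_loadings, second.factor_loadings
            nf = a.shape[1] + b.shape[1]
            genes = a.index.union(b.index, sort=False)
            loadings = pd.DataFrame(0.0, index=genes, columns=range(nf))
            loadings.iloc[:, a.shape[1]:] = b.reindex(genes).fillna(0.0).to_numpy()
            la = a.reindex(genes).fillna(0.0).to_numpy()
            # first truth wins where both load on a gene
            overlap = (np.abs(la).sum(axis=1) > 0)
            loadings.iloc[overlap, a.shape[1]:] = 0.0
            loadings.iloc[:, : a.shape[1]] = la
        elif first.factor_loadings is not None:
            loadings = first.factor_loadings.copy()
        elif second.factor_loadings is not None:
            loadings = second.factor_loadings.copy()
        return cls(
            informative_genes=sorted(set(first.informative_genes) | set(second.informative_genes)),
            concordant_genes=sorted(set(first.concordant_genes) | set(second.concordant_genes)),
            robust_genes=sorted(set(first.robust_genes) | set(second.robust_genes)),
            directions=directions,
            hazard_ratio=first.hazard_ratio or second.hazard_ratio,
            factor_loadings=loadings,
        )

    def to_json(self, path) -> None:
        payload = {
            "informative_genes": self.informative_genes,
            "concordant_genes": self.concordant_genes,
            "robust_genes": self.robust_genes,
            "directions": self.directions,
            "hazard_ratio": self.hazard_ratio,
        }
        if self.factor_loadings is not None:
            payload["factor_loadings"] = {
                "genes": list(self.factor_loadings.index),
                "values": self.factor_loadings.to_numpy().tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        loadings = None
        if "factor_loadings" in payload:
            fl = payload["factor_loadings"]
            loadings = pd.DataFrame(np.asarray(fl["values"], dtype=float), index=fl["genes"])
        return cls(
            informative_genes=payload["informative_genes"],
            concordant_genes=payload["concordant_genes"],
            robust_genes=payload["robust_genes"],
            directions={g: int(d) for g, d in payload["directions"].items()},
            hazard_ratio=payload["hazard_ratio"],
            factor_loadings=loadings,
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _assign_factors(
    rng: np.random.Generator, genes: list[str], concordant: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Each concordant gene loads on one random factor with a random sign."""
    loadings = pd.DataFrame(0.0, index=genes, columns=range(config.n_factors))
    if concordant:
        idx = rng.integers(0, config.n_factors, size=len(concordant))
        signs = rng.choice([-1.0, 1.0], size=len(concordant))
        for g, j, s in zip(concordant, idx, signs):
            loadings.at[g, j] = s * config.latent_loading
    return loadings


def simulate_cell_panel(
    config: SimulationConfig, drug_name: str = "drug_A"
) -> tuple[ExpressionMatrix, DrugActivityProfile, SyntheticTruth]:
    """Simulate a cell panel with drug activity and planted biomarkers.

    Activity is standard normal per line on a higher-is-sensitive scale.
    Informative genes follow ``baseline + direction * effect_size *
    standardized_activity + latent + noise``; concordant genes additionally
    share latent factors that a patient cohort can reuse; all other genes are
    pure noise around their baseline.
    """
    rng = _rng(config, _STREAM_PANEL)
    genes = _gene_ids(config.n_genes)
    lines = [f"CL{i:03d}" for i in range(1, config.n_cell_lines + 1)]

    informative = sorted(rng.choice(genes, size=config.n_informative, replace=False).tolist())
    # concordant set absorbs informative genes first (see SimulationConfig)
    if config.n_concordant <= config.n_informative:
        concordant = sorted(
            rng.choice(informative, size=config.n_concordant, replace=False).tolist()
        )
    else:
        rest = [g for g in genes if g not in informative]
        extra = rng.choice(
            rest, size=config.n_concordant - config.n_informative, replace=False
        ).tolist()
        concordant = sorted(informative + extra)

    directions = {g: int(d) for g, d in zip(informative, rng.choice([-1, 1], size=len(informative)))}

    activity = rng.standard_normal(config.n_cell_lines)
    act_std = (activity - activity.mean()) / activity.std(ddof=0)

    baseline = rng.normal(0.0, 1.0, size=config.n_genes)
    loadings = _assign_factors(rng, genes, concordant, config)
    factor_scores = rng.standard_normal((config.n_cell_lines, config.n_factors))

    X = np.tile(baseline[:, None], (1, config.n_cell_lines))
    X += loadings.to_numpy() @ factor_scores.T
    for g in informative:
        i = genes.index(g)
        X[i] += directions[g] * config.effect_size * act_std
    X += config.noise_sd * rng.standard_normal(X.shape)

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=lines), platform_tag="synthetic-panel")
    profile = DrugActivityProfile(drug_name, pd.Series(activity, index=lines))
    truth = SyntheticTruth(
        informative_genes=informative,
        concordant_genes=concordant,
        directions=directions,
        factor_loadings=loadings,
    )
    return expr, profile, truth


def simulate_patient_cohort(
    config: SimulationConfig, truth: SyntheticTruth, cohort_tag: str = "synthetic-cohort"
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Simulate a patient cohort sharing co-expression structure with a panel.

    Concordant genes reuse the panel's factor loadings (fresh patient-level
    factor scores); non-concordant genes receive their own independent factor
    structure of the same density. Responders and non-responders differ by
    ``effect_size * noise_sd`` on informative-and-concordant genes in the
    planted direction. Survival is exponential with the configured hazard
    ratio (non-responder vs responder) under administrative-plus-uniform
    independent censoring.
    """
    if truth is None or truth.factor_loadings is None:
        raise ValueError("simulate_patient_cohort requires the truth from simulate_cell_panel")
    rng = _rng(config, _STREAM_COHORT)
    genes = list(truth.factor_loadings.index)
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]
    n = config.n_patients

    responder = rng.random(n) < config.response_rate

    shared_loadings = truth.factor_loadings.to_numpy()
    n_shared_factors = shared_loadings.shape[1]
    factor_scores = rng.standard_normal((n, n_shared_factors))

    concordant = set(truth.concordant_genes)
    non_concordant = [g for g in genes if g not in concordant]
    own_loadings = _assign_factors(rng, genes, non_concordant, config)
    own_scores = rng.standard_normal((n, config.n_factors))

    baseline = rng.normal(0.0, 1.0, size=len(genes))
    X = np.tile(baseline[:, None], (1, n))
    X += shared_loadings @ factor_scores.T
    X += own_loadings.to_numpy() @ own_scores.T

    planted = [g for g in truth.informative_genes if g in concordant]
    for g in planted:
        i = genes.index(g)
        X[i, responder] += truth.directions[g] * config.effect_size * config.noise_sd
    X += config.noise_sd * rng.standard_normal(X.shape)

    # exponential survival; hazard ratio applies to non-responders
    rate_resp = np.log(2.0) / config.median_survival_responder
    rates = np.where(responder, rate_resp, rate_resp * config.hazard_ratio)
    t_event = rng.exponential(1.0 / rates)
    t_censor = np.minimum(
        config.censor_admin_months, rng.uniform(0.0, config.censor_uniform_max, size=n)
    )
    os_months = np.minimum(t_event, t_censor)
    event = t_event <= t_censor

    stages = rng.choice(["III", "IV"], size=n, p=[0.9, 0.1])
    debulking = rng.choice(["optimal", "suboptimal"], size=n, p=[0.55, 0.45])
    race = rng.choice(["White", "Black"], size=n, p=[0.93, 0.07])
    age = rng.normal(62.0, 7.0, size=n).round(1)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "response": np.where(responder, RESPONDER, NON_RESPONDER),
                "os_months": os_months,
                "event": event,
                "age": age,
                "stage": stages,
                "debulking": debulking,
                "race": race,
            },
            index=patients,
        )
    )
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=patients), platform_tag=cohort_tag)
    out_truth = replace(truth, hazard_ratio=config.hazard_ratio)
    return expr, clinical, out_truth


def simulate_ffpe_pair(
    expr: ExpressionMatrix,
    config: SimulationConfig,
    robust_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Degrade a frozen-tissue profile into an FFPE analogue.

    A fixed fraction of genes ("FFPE-robust") keeps its frozen values up to
    small measurement noise; the remaining genes lose their signal entirely
    (values redrawn around each gene's own mean/SD), emulating RNA
    degradation in formalin-fixed material. Pass ``robust_ids`` to reuse a
    previously drawn robust set — robustness is a property of a gene, so the
    same set must degrade every cohort within one study.
    """
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise ValueError("expression matrix must be non-empty")
    rng = _rng(config, _STREAM_FFPE)
    genes = expr.gene_ids
    if robust_ids is None:
        n_robust = int(round(config.ffpe_robust_fraction * len(genes)))
        robust_ids = sorted(rng.choice(genes, size=n_robust, replace=False).tolist())
    else:
        missing = set(robust_ids) - set(genes)
        if missing:
            raise ValueError(f"robust_ids not in matrix: {sorted(missing)[:5]}")
        robust_ids = sorted(robust_ids)

    robust_mask = np.isin(np.asarray(genes), np.asarray(robust_ids))
    X = expr.values.to_numpy(dtype=float).copy()
    small_noise = 0.3 * config.noise_sd
    X[robust_mask] += small_noise * rng.standard_normal(X[robust_mask].shape)

    lost = ~robust_mask
    if lost.any():
        mu = X[lost].mean(axis=1, keepdims=True)
        sd = X[lost].std(axis=1, ddof=0, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        X[lost] = mu + sd * rng.standard_normal(X[lost].shape)

    ffpe = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=expr.sample_ids),
        platform_tag=f"{expr.platform_tag}-ffpe" if expr.platform_tag else "ffpe",
    )
    return ffpe, SyntheticTruth(robust_genes=list(robust_ids))
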