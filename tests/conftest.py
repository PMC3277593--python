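import numpy as np
import pandas as pd
import pytest

from coxen import (
    ClinicalTable,
    DrugActivityProfile,
    ExpressionMatrix,
    SensitivityLabels,
    SimulationConfig,
    simulate_cell_panel,
    simulate_patient_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=120, n_cell_lines=40, n_patients=60, n_informative=15, n_concordant=40, seed=11
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_cell_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    _, _, truth = small_panel
    return simulate_patient_cohort(small_config, truth)


def make_expression(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))


def make_labels(sensitive_ids, resistant_ids) -> SensitivityLabels:
    lab = {s: "sensitive" for s in sensitive_ids}
    lab.update({r: "resistant" for r in resistant_ids})
    return SensitivityLabels(pd.Series(lab, dtype=object))


def make_clinical(sample_ids, responder_flags, os_months=None, events=None) -> ClinicalTable:
    n = len(sample_ids)
    return ClinicalTable(
        pd.DataFrame(
            {
                "response": ["responder" if f else "non_responder" for f in responder_flags],
                "os_months": os_months if os_months is not None else np.ones(n),
                "event": events if events is not None else [True] * n,
            },
            index=list(sample_ids),
        )
    )


def make_activity(values, ids=None, drug="drug") -> DrugActivityProfile:
    ids = ids or [f"c{i}" for i in range(len(values))]
    return DrugActivityProfile(drug, pd.Series(np.asarray(values, dtype=float), index=ids))
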