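import numpy as np
import pandas as pd
import pytest

from erss_pipeline.pipeline_io import ClinicalTable, ExpressionMatrix
from erss_pipeline.synthdata import CohortSpec, simulate_expression_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted-signal cohort shared by read-only tests."""
    spec = CohortSpec(
        n_tumor=150, n_normal=60, n_genes=300, n_de_up=40, n_de_down=40,
        cluster_A_size=8, cluster_B_size=4, seed=7,
    )
    return simulate_expression_cohort(spec)


@pytest.fixture(scope="session")
def tumor_view(small_cohort):
    expr, clin, truth = small_cohort
    tumors = [s for s in expr.sample_ids if clin.data.loc[s, "group"] == "tumor"]
    return ExpressionMatrix(expr.values[tumors]), clin.aligned_to(tumors), truth


def toy_expression(values: np.ndarray, prefix: str = "g") -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def toy_clinical(times, status, **covariates) -> ClinicalTable:
    n = len(times)
    data = {"sample_id": [f"s{j}" for j in range(n)], "time": times, "status": status}
    data.update(covariates)
    return ClinicalTable(pd.DataFrame(data))
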