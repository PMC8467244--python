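import pandas as pd
import pytest

from itac.datamodel import ExpressionMatrix, SampleSheet
from itac.normalization import normalize_pipeline
from itac.simulate import (
    ExpressionScenario,
    MethylationScenario,
    generate_expression,
    generate_methylation,
)


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {"group": ["N", "E", "C", "T"]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="id"),
        )
    )


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            [[100.0, 200.0, 300.0, 400.0],
             [50.0, 60.0, 70.0, 80.0],
             [10.0, 10.0, 10.0, 10.0]],
            index=pd.Index(["g1", "g2", "g3"], name="id"),
            columns=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture(scope="session")
def small_scenario() -> ExpressionScenario:
    """Shrunk expression scenario for fast pipeline tests."""
    return ExpressionScenario(
        n_genes=400,
        n_per_group={"N": 6, "E": 6, "C": 6, "T": 6},
        diff_archetype_size=30,
    )


@pytest.fixture(scope="session")
def small_expression(small_scenario):
    return generate_expression(small_scenario, seed=7)


@pytest.fixture(scope="session")
def default_expression():
    return generate_expression(ExpressionScenario(), seed=7)


@pytest.fixture(scope="session")
def default_normalized(default_expression):
    expr, sheet, truth = default_expression
    corrected, norm = normalize_pipeline(expr)
    return corrected, norm, sheet, truth


@pytest.fixture(scope="session")
def small_meth_scenario() -> MethylationScenario:
    return MethylationScenario(n_probes=4000, n_control=24)


@pytest.fixture(scope="session")
def small_methylation(small_meth_scenario):
    return generate_methylation(small_meth_scenario, seed=7)
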