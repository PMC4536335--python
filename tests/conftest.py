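import numpy as np
import pandas as pd
import pytest

from synergyscreen import (
    ExpressionMatrix,
    MedianEffectFit,
    SimulationConfig,
    gen_expression_phenotype,
)


@pytest.fixture
def simple_fit() -> MedianEffectFit:
    return MedianEffectFit(Dm=2.0, m=1.5)


@pytest.fixture
def unit_fit() -> MedianEffectFit:
    return MedianEffectFit(Dm=1.0, m=1.0)


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.standard_normal((10, 20)),
        index=[f"G{i}" for i in range(10)],
        columns=[f"S{i}" for i in range(20)],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def planted_screen():
    """Planted-signal simulation plus its ground truth (47 signal, 103 null, n=30)."""
    config = SimulationConfig(seed=42)
    expr, ic50, signal_genes = gen_expression_phenotype(config)
    return expr, ic50, signal_genes
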