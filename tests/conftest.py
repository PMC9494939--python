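import numpy as np
import pytest

from poroshell import (
    NoiseSpec,
    UnifiedModel,
    crossover_prefactor,
    instrument_grid,
    simulate_curve,
)


@pytest.fixture(scope="session")
def grid():
    return instrument_grid()


@pytest.fixture(scope="session")
def canonical_model(grid):
    """Level-1 model representative of the emulsion samples (Rg 150 Å, P 2.5)."""
    return UnifiedModel.single_level(
        G=1.0, Rg=150.0, B=crossover_prefactor(1.0, 150.0, 2.5, grid=grid), P=2.5
    )


@pytest.fixture(scope="session")
def canonical_curve(canonical_model, grid):
    return simulate_curve(canonical_model, grid)


@pytest.fixture()
def noisy_curve(canonical_model, grid):
    return simulate_curve(canonical_model, grid, NoiseSpec("multiplicative", 0.02, 123))
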