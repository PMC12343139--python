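import numpy as np
import pytest

from cdrmotifs import MotifSpec, SolverOptions


@pytest.fixture
def iffl1_toy() -> MotifSpec:
    """x' = -x + u, y' = -10xy + u from x(0)=0, y(0)=1/10."""
    return MotifSpec("IFFL1", gamma=10.0, x0=0.0, y0=0.1)


@pytest.fixture
def ifb_toy() -> MotifSpec:
    """x' = x(y - 6), y' = u/x - y from x(0)=0.1, y(0)=6."""
    return MotifSpec("IFB", delta=6.0, x0=0.1, y0=6.0)


@pytest.fixture
def normalized_iffl1() -> MotifSpec:
    """Unit-parameter IFFL1: x' = -x + u, y' = -xy + u, y(0)=1."""
    return MotifSpec("IFFL1", x0=0.0, y0=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250923)


@pytest.fixture
def fast_opts() -> SolverOptions:
    """Looser tolerance for randomized sweeps (still far below any
    asserted effect size)."""
    return SolverOptions(rtol=1e-8, atol=1e-11, n_points=60)
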