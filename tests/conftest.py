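"""Shared fixtures: cost models and the frozen study parameterizations."""

import numpy as np
import pytest

from msatmap import CostModel, SimParams, chain_cost_model, default_cost_model


@pytest.fixture
def uniform3() -> CostModel:
    """Uniform-cost model over {a, b, c}."""
    return default_cost_model(("a", "b", "c"))


@pytest.fixture
def history_costs() -> CostModel:
    """The cost model of the worked derivation example:
    d(a,b)=d(b,c)=1, d(a,c)=2, c_dup=0.5."""
    d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    return CostModel(alphabet=("a", "b", "c"), d_M=d, c_dup=0.5, c_ins=1.5, c_del=1.5)


def random_cost_model(rng: np.random.Generator, k: int = 2,
                      metric: bool | None = None) -> CostModel:
    """A random (possibly non-metric) cost model over the first k letters."""
    alphabet = tuple("abcd"[:k])
    d = rng.uniform(0.1, 3.0, size=(k, k))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return CostModel(
        alphabet=alphabet, d_M=d,
        c_dup=float(rng.uniform(0.1, 1.0)),
        c_ins=float(rng.uniform(0.3, 2.5)),
        c_del=float(rng.uniform(0.3, 2.5)),
    )


# ---------------------------------------------------------------------------
# frozen study conditions for the parameter-recovery analyses
# ---------------------------------------------------------------------------

def bias_study_params(beta: float, seed: int) -> SimParams:
    """Direction-recovery study: lineages evolved by direction-restricted
    tandem duplication only (20 maps x 30 events in the tests)."""
    return SimParams(beta=beta, seed=seed, p_dup=1.0, p_mut=0.0, p_indel=0.0)


def polarity_study_params(mut_end_bias: float, seed: int) -> SimParams:
    """Polarity-recovery study: mutation-dominated evolution with the
    positional skew under test."""
    return SimParams(n_events=30, p_dup=0.3, p_mut=0.6, p_indel=0.1,
                     mut_end_bias=mut_end_bias, seed=seed)


def study_costs() -> CostModel:
    """Chain-metric cost model matching the generator's local mutations."""
    return chain_cost_model(SimParams().alphabet)
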