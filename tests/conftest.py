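import numpy as np
import pytest

from panelmsm.model_core import (
    BaselineDef,
    ModelSpec,
    StateGraph,
    Term,
    TransitionModel,
)


@pytest.fixture
def two_state_spec():
    """Irreversible 1 -> 2 with a constant baseline rate."""
    graph = StateGraph(("1", "2"), (("1", "2"),))
    return ModelSpec(
        graph=graph,
        transitions={("1", "2"): TransitionModel(("1", "2"), "lam")},
        baselines={"lam": BaselineDef("lam")},
    )


@pytest.fixture
def two_state_covariate_spec():
    graph = StateGraph(("1", "2"), (("1", "2"),))
    return ModelSpec(
        graph=graph,
        transitions={("1", "2"): TransitionModel(("1", "2"), "lam", (Term("x", "beta"),))},
        baselines={"lam": BaselineDef("lam")},
    )


@pytest.fixture
def three_state_spec():
    """Adjacent-reversible 3-state chain with constant baselines."""
    trs = (("1", "2"), ("2", "1"), ("2", "3"), ("3", "2"))
    graph = StateGraph(("1", "2", "3"), trs)
    return ModelSpec(
        graph=graph,
        transitions={tr: TransitionModel(tr, f"lam{tr[0]}{tr[1]}") for tr in trs},
        baselines={f"lam{a}{b}": BaselineDef(f"lam{a}{b}") for a, b in trs},
    )


@pytest.fixture
def three_state_params():
    return {"lam12": 0.2, "lam21": 0.1, "lam23": 0.3, "lam32": 0.4}
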