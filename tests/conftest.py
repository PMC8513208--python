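import numpy as np
import pytest

from dndea.panel import PanelDataset, VariableSpec, builtin_oecd7_fixture


@pytest.fixture(scope="session")
def fixture_panel():
    return builtin_oecd7_fixture()


@pytest.fixture
def toy_panel():
    """Two DMUs, one division/period: A=(input 1, output 1), B=(input 2, output 1)."""
    schema = [VariableSpec("x", "d", "input"), VariableSpec("y", "d", "output")]
    values = {
        ("A", "x", "t1"): 1.0,
        ("A", "y", "t1"): 1.0,
        ("B", "x", "t1"): 2.0,
        ("B", "y", "t1"): 1.0,
    }
    return PanelDataset(["A", "B"], ["t1"], ["d"], schema, values)


def random_small_panel(seed, n_dmus=3, n_divisions=2, n_periods=2, with_link=True, with_carry=True):
    """Small random network panel for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    divisions = [f"k{i}" for i in range(n_divisions)]
    periods = [f"t{i}" for i in range(n_periods)]
    dmus = [f"D{i}" for i in range(n_dmus)]
    schema = []
    for k in divisions:
        schema.append(VariableSpec(f"x_{k}", k, "input"))
        schema.append(VariableSpec(f"y_{k}", k, "output"))
    if with_link and n_divisions >= 2:
        mode = ["as_output", "as_input"][seed % 2]
        schema.append(VariableSpec("z", divisions[0], "link", divisions[0], divisions[1], mode))
    if with_carry and n_periods >= 2:
        schema.append(VariableSpec("c", divisions[0], "carry_over", carry_class="bad"))
    values = {
        (d, v.name, t): float(rng.uniform(1.0, 10.0))
        for d in dmus
        for v in schema
        for t in periods
    }
    return PanelDataset(dmus, periods, divisions, schema, values)
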