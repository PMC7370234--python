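import numpy as np
import pytest

from trailstrat import PanelSpec, RunConfig, gen_panel


@pytest.fixture
def tiny_panel_text(tmp_path):
    """Hand-written 3x2 panel file."""
    path = tmp_path / "panel.tsv"
    path.write_text("sample\tXIAP\tBax\ns1\t1.0\t4.0\ns2\t2.0\t5.0\ns3\t3.0\t9.0\n")
    return path


@pytest.fixture
def random_panel():
    """Factory for random positive panels of arbitrary shape."""

    def make(n, p, seed=0):
        rng = np.random.default_rng(seed)
        from trailstrat import ExpressionPanel

        values = rng.lognormal(mean=2.0, sigma=1.0, size=(n, p))
        return ExpressionPanel(
            tuple(f"s{i}" for i in range(n)), tuple(f"prot{j}" for j in range(p)), values
        )

    return make


@pytest.fixture
def strong_panel():
    """Well-separated two-class panel: 5-sd shift on every protein."""
    return gen_panel(PanelSpec(effect_size=5.0, n_informative=19, seed=7))


@pytest.fixture
def default_panel():
    """Study-condition panel: 12+4 samples x 19 proteins, moderate effect."""
    return gen_panel(PanelSpec(seed=11))


@pytest.fixture
def config():
    return RunConfig()


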