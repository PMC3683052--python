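import numpy as np
import pytest

from topnet import synthdata
from topnet.io_formats import ExpressionStudy, PPIGraph


@pytest.fixture(scope="session")
def tiny_fixture():
    return synthdata.make_fixture("tiny")


@pytest.fixture(scope="session")
def paper_shaped_fixture():
    return synthdata.make_fixture("paper_shaped")


@pytest.fixture
def small_study():
    """5 genes x 8 samples, 2 states, hand-controlled profiles."""
    rng = np.random.default_rng(7)
    genes = ["A", "B", "C", "D", "E"]
    samples = [f"s{i}" for i in range(8)]
    design = {s: ("X" if i < 4 else "Y") for i, s in enumerate(samples)}
    base = rng.normal(7, 1, size=(5, 8))
    base[1] = base[0] + 0.01 * rng.standard_normal(8)  # B tracks A
    return ExpressionStudy(genes=genes, samples=samples, values=base, design=design)


@pytest.fixture
def small_ppi():
    return PPIGraph(edges={("A", "B"), ("B", "C"), ("C", "D"), ("A", "E")})
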