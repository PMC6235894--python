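import numpy as np
import pandas as pd
import pytest

from crossig.io import ClinicalTable, ExpressionMatrix
from crossig.signature import CONTROL, PERTURBED
from crossig.simulate import MouseSimConfig, simulate_mouse


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values=values, species="human", cohort="toy")


@pytest.fixture
def two_class_matrix():
    """12 samples, 50 genes; genes 0-4 shifted strongly in the perturbed class."""
    rng = np.random.default_rng(7)
    n_per = 6
    values = rng.normal(8.0, 0.4, size=(50, 2 * n_per))
    values[:5, :n_per] += 3.0
    cols = [f"p{i}" for i in range(n_per)] + [f"c{i}" for i in range(n_per)]
    m = ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"g{i}" for i in range(50)], columns=cols),
        species="mouse",
        cohort="toy",
        collapsed=True,
    )
    labels = pd.Series([PERTURBED] * n_per + [CONTROL] * n_per, index=cols)
    return m, labels


@pytest.fixture
def mouse_sim():
    cfg = MouseSimConfig(n_genes=800, n_de=40, n_per_arm=4, seed=11)
    return simulate_mouse(cfg)


@pytest.fixture
def clinical_table() -> ClinicalTable:
    rng = np.random.default_rng(3)
    n = 40
    return ClinicalTable(
        data=pd.DataFrame(
            {
                "os_months": rng.exponential(30, n).round(2),
                "os_event": rng.integers(0, 2, n),
                "stage": rng.choice(["I", "II", "III"], n),
                "tumor_size": rng.lognormal(1.0, 0.3, n),
                "afp_high": rng.integers(0, 2, n),
            },
            index=[f"pt{i}" for i in range(n)],
        )
    )
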