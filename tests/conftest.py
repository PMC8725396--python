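"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pandas as pd
import pytest

from petalmorph.simulate import (
    demo_expression_spec,
    gen_counts,
    gen_epidermis,
    scenario_preset,
)


@pytest.fixture(scope="session")
def pedomorphic_data():
    """Pedomorphic epidermis sheet at the measurement scale (10 cells/image)."""
    spec = scenario_preset("pedomorphic", seed=1, cells_per_image=10)
    return gen_epidermis(spec)


@pytest.fixture(scope="session")
def non_pedomorphic_data():
    spec = scenario_preset("non_pedomorphic", seed=1, cells_per_image=10)
    return gen_epidermis(spec)


@pytest.fixture(scope="session")
def demo_counts():
    """Two-species count dataset with the bundled planted-signature demo."""
    return gen_counts(demo_expression_spec(seed=11))


@pytest.fixture()
def plus_polygon():
    """3x3 square minus the four 1x1 corners (12-vertex plus shape):
    area 5, hull area 7, lobeyness 2/7."""
    from petalmorph.geometry import Polygon

    verts = np.array([
        (1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2),
        (2, 3), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1),
    ], dtype=float)
    return Polygon(verts)


def toy_sample_sheet(n1=3, n2=3, species="X"):
    cols = [f"{species}_bud_{i}" for i in range(n1)] + [
        f"{species}_mature_{i}" for i in range(n2)]
    info = pd.DataFrame({
        "sample": cols,
        "species": [species] * (n1 + n2),
        "stage": ["bud"] * n1 + ["mature"] * n2,
    })
    return info.set_index("sample", drop=False)


def nb_matrix(n_genes, n1=3, n2=3, mean_log=np.log(200), alpha=0.05,
              lfc=None, seed=0, species="X"):
    """NB count matrix for a bud-vs-mature toy contrast; lfc applies to the
    bud group."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean_log, 1.2, n_genes)
    mu = np.tile(base[:, None], (1, n1 + n2))
    if lfc is not None:
        fac = 2.0 ** (np.asarray(lfc, dtype=float))
        mu[:, :n1] *= fac[:, None] if fac.ndim else fac
    if alpha < 1e-8:
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
    info = toy_sample_sheet(n1, n2, species)
    counts = pd.DataFrame(y, index=[f"g{i:04d}" for i in range(n_genes)],
                          columns=info.index)
    return counts, info
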