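import numpy as np
import pytest

from ttfdose import pipeline
from ttfdose.tissue_model import TissueTable


@pytest.fixture(scope="session")
def props():
    return TissueTable.default()


@pytest.fixture(scope="session")
def fixture_tables(props):
    """Three-case comparison tables for both shipped fixtures.

    Solved once per session and shared by the directional acceptance tests;
    only the metric summaries are retained (the field volumes are large).
    """
    tables = {}
    for name in ("superficial", "deep"):
        cfg = pipeline.fixture_config(name)
        tables[name] = pipeline.compare_cases(cfg, props=props)
    return tables


def dirichlet_plates_z(shape):
    """Dirichlet faces covering the two z boundary planes of a full grid."""
    from ttfdose.em_solver import BoundaryFaces

    idx = np.arange(int(np.prod(shape))).reshape(shape)
    lo = idx[:, :, 0].ravel()
    hi = idx[:, :, -1].ravel()
    n = lo.size
    return BoundaryFaces(
        np.concatenate([lo, hi]),
        np.full(2 * n, 2),
        np.concatenate([np.full(n, -1), np.full(n, 1)]),
        np.concatenate([np.full(n, 0j), np.zeros(n, complex)]),
    )


def plate_system(kappa, spacing_mm, voltage=80.0):
    """Assemble a full-grid slab driven by plate electrodes on the z faces."""
    from ttfdose import em_solver as em

    shape = kappa.shape
    d = dirichlet_plates_z(shape)
    d.value[: d.value.size // 2] = voltage
    mask = np.ones(shape, dtype=bool)
    return em.assemble(kappa, mask, spacing_mm, dirichlet=d)
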