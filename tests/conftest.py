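import numpy as np
import pytest

from tetrd.engine import build_tables
from tetrd.mesh import TetMesh, compute_geometry, generate_cuboid_mesh
from tetrd.model import ModelSpec, Reaction, Species, benchmark_model


@pytest.fixture(scope="session")
def cube6():
    """Unit cube split into 6 Kuhn tets."""
    return generate_cuboid_mesh((1, 1, 1), (1, 1, 1))


@pytest.fixture(scope="session")
def bench_model():
    return benchmark_model()


@pytest.fixture(scope="session")
def bar60():
    """Coarse 60-tet mesh of the 10x10x100 um^3 box (cells 10x10x10)."""
    return generate_cuboid_mesh((10, 10, 100), (1, 1, 10))


@pytest.fixture(scope="session")
def bench_tables60(bar60, bench_model):
    return build_tables(bar60, compute_geometry(bar60), bench_model)


@pytest.fixture(scope="session")
def bench_tables6(cube6, bench_model):
    return build_tables(cube6, compute_geometry(cube6), bench_model)


@pytest.fixture(scope="session")
def single_tet():
    """One isolated tet with volume ~1 um^3 (edge 1.817 um)."""
    a = 1.8171205928321397  # (6)^(1/3)
    verts = np.array([[0, 0, 0], [a, 0, 0], [0, a, 0], [0, 0, a]], dtype=float)
    return TetMesh(verts, np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def two_tet():
    """Two mirror-image tets sharing one interior face, equal volumes."""
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [2 / 3, 2 / 3, 2 / 3]],
        dtype=float,
    )
    return TetMesh(verts, np.array([[0, 1, 2, 3], [4, 1, 2, 3]]))


@pytest.fixture(scope="session")
def ab_model():
    """Single reversible binding A+B<->C, immobile species."""
    return ModelSpec(
        [Species("A", 0.0), Species("B", 0.0), Species("C", 0.0)],
        [Reaction({"A": 1, "B": 1}, {"C": 1}, 1000.0),
         Reaction({"C": 1}, {"A": 1, "B": 1}, 100.0)],
    )


@pytest.fixture(scope="session")
def diffusion_only_model():
    """One diffusive species, no reactions."""
    return ModelSpec([Species("X", 100.0)], [])


def uniform_counts(mesh, model, totals, seed=0):
    from tetrd.ssa import place_uniform

    tables = build_tables(mesh, compute_geometry(mesh), model)
    return place_uniform(tables, totals, np.random.default_rng(seed))
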