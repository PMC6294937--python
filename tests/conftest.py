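import numpy as np
import pytest

from capsidlattice import capsid_models as cm
from capsidlattice import tomo_sim as ts


@pytest.fixture(scope="session")
def cone_model():
    return cm.generate_fullerene_cone(n_hex_target=200, seed=1)


@pytest.fixture(scope="session")
def shell_t3():
    return cm.generate_closed_shell(1, 1, radius=15.0)


@pytest.fixture(scope="session")
def shell_t7():
    return cm.generate_closed_shell(2, 1, radius=22.0)


@pytest.fixture(scope="session")
def immature_model():
    return cm.generate_immature_shell(radius=24.0, spacing=8.0,
                                      gap_fraction=0.15, n_small_defects=2,
                                      seed=3)


@pytest.fixture(scope="session")
def nested_model():
    return cm.generate_nested_cores([
        {"morphology": "closed_polyhedron", "h": 2, "k": 1, "radius": 28.0},
        {"morphology": "closed_polyhedron", "h": 1, "k": 1, "radius": 13.0},
    ])


@pytest.fixture(scope="session")
def mature_template():
    return ts.make_template("mature", spacing=10.0, voxel_size=5.4, box=24)


@pytest.fixture(scope="session")
def immature_template():
    return ts.make_template("immature", spacing=8.0, voxel_size=5.4, box=24)


@pytest.fixture(scope="session")
def pentamer_template():
    return ts.make_template("pentamer", spacing=10.0, voxel_size=5.4, box=24)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def immature_run(tmp_path_factory):
    from capsidlattice.pipeline import RunConfig, run_demo
    out = tmp_path_factory.mktemp("demo_immature")
    cfg = RunConfig(seed=1, immature_radius_nm=20.0)
    summary = run_demo("immature", cfg, out_dir=str(out))
    return out, summary


@pytest.fixture(scope="session")
def mature_run(tmp_path_factory):
    from capsidlattice.pipeline import RunConfig, run_demo
    out = tmp_path_factory.mktemp("demo_mature")
    cfg = RunConfig(seed=1)
    summary = run_demo("mature_closed", cfg, out_dir=str(out))
    return out, summary


def flat_hex_patch(n: int = 8, spacing: float = 10.0) -> np.ndarray:
    """Planar hexagonal lattice patch (n x n sites)."""
    rows = []
    for j in range(n):
        for i in range(n):
            rows.append([(i + 0.5 * (j % 2)) * spacing,
                         j * spacing * np.sqrt(3) / 2, 0.0])
    return np.asarray(rows)
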