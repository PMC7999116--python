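import numpy as np
import pytest
import trimesh

from airwaymorph.mesh import make_mesh


def pytest_configure(config):
    try:
        from hypothesis import HealthCheck, settings

        settings.register_profile(
            "ci",
            derandomize=True,
            max_examples=25,
            deadline=None,
            suppress_health_check=[HealthCheck.too_slow],
        )
        settings.load_profile("ci")
    except ImportError:
        pass


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


def ngon_cylinder(n: int, radius: float, height: float) -> trimesh.Trimesh:
    """Capped n-gon prism with z in [0, height] (exact-volume oracle shape)."""
    cyl = trimesh.creation.cylinder(radius=radius, height=height, sections=n)
    return make_mesh(cyl.vertices + [0, 0, height / 2], cyl.faces)


def ngon_prism_volume(n: int, radius: float, height: float) -> float:
    return 0.5 * n * radius**2 * np.sin(2 * np.pi / n) * height


def ngon_area(n: int, radius: float) -> float:
    return 0.5 * n * radius**2 * np.sin(2 * np.pi / n)


@pytest.fixture(scope="session")
def cylinder720():
    return ngon_cylinder(720, 10.0, 50.0)


@pytest.fixture(scope="session")
def fine_tube():
    """Tube with fine z-resolution (shape of the synthetic airway meshes)."""
    from airwaymorph.synth import AirwayProfile, _tube_mesh

    return _tube_mesh(AirwayProfile())
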