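import numpy as np
import pytest

from panicle3d import ColoredPointCloud
from panicle3d.synthetic import (
    SyntheticPanicleSpec,
    generate_panicle,
    generate_primitive,
)


@pytest.fixture(scope="session")
def sphere_cloud():
    """Dense unit sphere shell: every silhouette is a disc of area pi."""
    return generate_primitive("sphere_shell", {"radius": 1.0}, n_points=50000, seed=11)


@pytest.fixture(scope="session")
def small_sphere_cloud():
    return generate_primitive("sphere_shell", {"radius": 1.0}, n_points=4000, seed=12)


@pytest.fixture(scope="session")
def cylinder_cloud():
    """Solid cylinder along Z, r=0.5 h=10: axial silhouettes are 2rh = 10."""
    return generate_primitive(
        "cylinder", {"radius": 0.5, "height": 10.0}, n_points=50000, seed=13
    )


@pytest.fixture(scope="session")
def panicle_with_clutter():
    """Default synthetic panicle plus a gray clutter cluster, with truth."""
    spec = SyntheticPanicleSpec(
        clutter=[((25.0, 0.0, -5.0), 3000, "gray")], seed=21
    )
    return generate_panicle(spec)


@pytest.fixture(scope="session")
def panicle_cloud(panicle_with_clutter):
    cloud, truth = panicle_with_clutter
    return cloud.subset(truth.is_panicle)


@pytest.fixture
def tiny_cloud():
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 2.0]])
    colors = np.array([[10.0, 200.0, 30.0], [120.0, 120.0, 120.0], [250.0, 40.0, 5.0]])
    return ColoredPointCloud(coords, colors)


def small_panicle_spec(seed: int, clutter_size: int = 800) -> SyntheticPanicleSpec:
    """A reduced panicle used where many replicates are generated."""
    return SyntheticPanicleSpec(
        n_primary_branches=6,
        spikelets_per_branch=5,
        points_per_spikelet=40,
        clutter=[((20.0, 5.0, -4.0), clutter_size, "gray")],
        seed=seed,
    )
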