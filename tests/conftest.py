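import numpy as np
import pytest

from pnnmesh import (
    LatticeParams,
    RenderParams,
    generate_lattice,
    make_patch_dataset,
    render_scene,
)


@pytest.fixture(scope="session")
def small_lattice():
    """20 meshes in a 256x256 domain."""
    return generate_lattice(
        LatticeParams(n_meshes=20, mean_mesh_diameter=26, domain_size=(256, 256)), seed=0
    )


@pytest.fixture(scope="session")
def clean_scene(small_lattice):
    """Noise-free high-contrast rendering of the small lattice."""
    return render_scene(small_lattice, RenderParams.for_regime("high_contrast").noiseless(), seed=0)


@pytest.fixture(scope="session")
def noisy_scene(small_lattice):
    return render_scene(small_lattice, RenderParams.for_regime("high_contrast"), seed=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """~40-patch corpus on a small scene (clean, fast)."""
    lat = LatticeParams(n_meshes=50, mean_mesh_diameter=26, domain_size=(384, 384))
    rend = RenderParams.for_regime("high_contrast").noiseless()
    return make_patch_dataset(1, lat, rend, patch_size=128, seed=0)


def square_contour(side=10.0, origin=(0.0, 0.0)):
    from pnnmesh import MeshContour

    x0, y0 = origin
    return MeshContour(
        vertices=np.array(
            [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]]
        )
    )


def regular_ngon(n, radius=1.0, center=(0.0, 0.0)):
    from pnnmesh import MeshContour

    th = 2 * np.pi * np.arange(n) / n
    return MeshContour(
        vertices=np.column_stack(
            [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
        )
    )
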