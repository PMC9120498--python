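import numpy as np
import pandas as pd
import pytest

from specdiv import io, preprocess, scene


def coarse_grid(step: float = 10.0) -> np.ndarray:
    """Full spectral range at reduced band density, for replicate-heavy tests."""
    return np.arange(380.0, 2510.0 + step / 2, step)


@pytest.fixture(scope="session")
def small_scene():
    """One rendered 6-plot scene on the coarse grid, with its inventory."""
    cfg = scene.SceneConfig(
        n_plots=6, gradient_strength=12.0, seed=11, wavelengths=coarse_grid()
    )
    scn, inventory, tree = scene.simulate_study(cfg, n_species=10, seed=11)
    return scn, inventory, tree


@pytest.fixture(scope="session")
def small_site(small_scene):
    """Preprocessed pixel matrices for the small scene."""
    scn, inventory, tree = small_scene
    cube = io.scene_to_cube(scn)
    kept, rejected = preprocess.preprocess_site(cube)
    return scn, inventory, tree, kept, rejected


def constant_cube(values: np.ndarray, ny: int = 4, nx: int = 4) -> io.SpectralCube:
    """Cube whose every pixel carries the same spectrum."""
    values = np.asarray(values, dtype=float)
    data = np.broadcast_to(values, (ny, nx, values.size)).copy()
    wl = np.linspace(400.0, 2400.0, values.size + 2)[1:-1]
    return io.SpectralCube(data=data, wavelengths=wl)


def cover_frame(array, plots=None, species=None) -> pd.DataFrame:
    a = np.asarray(array, dtype=float)
    plots = plots or [f"p{i}" for i in range(a.shape[0])]
    species = species or [f"s{j}" for j in range(a.shape[1])]
    return pd.DataFrame(a, index=pd.Index(plots, name="plot_id"), columns=species)
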