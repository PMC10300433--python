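import numpy as np
import pytest

from branchmorph.synthetic import (
    BifurcationParams,
    ImagingParams,
    ScenarioParams,
    generate_bifurcation_scenario,
    generate_elongation_scenario,
    render_stack,
)


@pytest.fixture(scope="session")
def elongation_gt():
    params = ScenarioParams(n_cells=300, n_frames=20, seed=11)
    return generate_elongation_scenario(params)


@pytest.fixture(scope="session")
def bifurcation_gt():
    params = ScenarioParams(
        n_cells=400,
        n_frames=24,
        seed=7,
        bifurcation=BifurcationParams(t0_frame=12, widening_frames=4),
    )
    return generate_bifurcation_scenario(params)


@pytest.fixture(scope="session")
def sparse_scene():
    """Well-separated nuclei on a jittered grid: easy detection target."""
    rng = np.random.default_rng(42)
    import pandas as pd

    from branchmorph.datatypes import LandmarkSet
    from branchmorph.synthetic import GroundTruth, ScenarioParams, _Shape

    nx, ny, nz = 5, 5, 2
    spacing = 18.0
    pts, cls = [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = np.array([20 + i * spacing, 20 + j * spacing, 12 + k * spacing])
                p += rng.uniform(-2, 2, 3)
                pts.append(p)
                cls.append("green" if rng.uniform() < 0.5 else "red")
    pts = np.array(pts)
    cells = pd.DataFrame(
        {
            "frame": 0,
            "id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "cls": cls,
        }
    )
    lms = LandmarkSet.from_records([(0, "leading_edge", 120.0, 50.0, 20.0)])
    params = ScenarioParams(n_cells=len(pts), n_frames=2, seed=42)
    return GroundTruth(cells=cells, landmarks=lms, params=params)


@pytest.fixture(scope="session")
def rendered_sparse(sparse_scene):
    return render_stack(
        sparse_scene,
        ImagingParams(voxel_size=(2.0, 0.7, 0.7), nucleus_sigma=2.0),
    )


@pytest.fixture(scope="session")
def rendered_sparse_clean(sparse_scene):
    return render_stack(
        sparse_scene,
        ImagingParams(
            voxel_size=(2.0, 0.7, 0.7),
            nucleus_sigma=2.0,
            photon_scale=200.0,
            gaussian_noise_sd=0.0,
            poisson=False,
        ),
    )
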