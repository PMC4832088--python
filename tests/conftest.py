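import numpy as np
import pytest

import vbmpattern as vp


@pytest.fixture(scope="session")
def strong_cohort():
    """Default-size cohort (22/27, 32^3 grid) with the three planted
    clusters at strong amplitude."""
    cfg = vp.CohortConfig(clusters=vp.default_clusters(), seed=7)
    volumes, phenotypes = vp.generate_cohort(cfg)
    return cfg, volumes, phenotypes


@pytest.fixture(scope="session")
def strong_matrix(strong_cohort):
    cfg, volumes, phenotypes = strong_cohort
    labels = [p.label for p in phenotypes]
    mask = vp.compute_mask(volumes)
    return vp.assemble_matrix(volumes, labels, mask)


@pytest.fixture(scope="session")
def strong_results(strong_matrix):
    model = vp.PatternClassificationModel(
        strong_matrix, vp.CVConfig(n_iterations=300, seed=7)
    )
    return model.fit()


@pytest.fixture()
def tiny_matrix():
    """Handmade 4-subject matrix: 6 voxels, the first two carry a clean
    group difference."""
    rng = np.random.default_rng(0)
    values = rng.normal(0.5, 0.01, size=(4, 6))
    values[:2, :2] += 0.3  # cases larger on voxels 0 and 1
    voxel_index = np.array(
        [[i, j, 0] for i in range(3) for j in range(2)]
    )
    return vp.VoxelMatrix(
        values=values,
        voxel_index=voxel_index,
        labels=np.array(["case", "case", "control", "control"]),
        affine=np.eye(4),
        grid_shape=(3, 2, 1),
    )


def make_separable_matrix(
    n_cases=6, n_controls=7, n_voxels=100, n_signal=10, gap=0.5, seed=0
):
    """Matrix with ``n_signal`` leading columns carrying a large clean
    group difference; used where an exactly-known selection is needed.

    With 10 signal columns in 100, the z-transformed difference image
    puts the signal columns near z ~ +3 and the noise columns near
    z ~ -0.33, so a 1.5 threshold selects exactly the signal block.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(0.5, 0.02, size=(n_cases + n_controls, n_voxels))
    values[:n_cases, :n_signal] += gap
    grid = (n_voxels, 1, 1)
    voxel_index = np.array([[i, 0, 0] for i in range(n_voxels)])
    labels = np.array(["case"] * n_cases + ["control"] * n_controls)
    return vp.VoxelMatrix(
        values=values,
        voxel_index=voxel_index,
        labels=labels,
        affine=np.eye(4),
        grid_shape=grid,
    )
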