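import numpy as np
import pytest
import trimesh

from radshape.pipeline import PipelineConfig, run_pipeline
from radshape.synthetic import (
    PopulationConfig,
    calibrated_bone_params,
    generate_bone,
)


@pytest.fixture(scope="session")
def bone():
    """Default calibrated right bone at 1.0 mm edges, noise-free."""
    return generate_bone(calibrated_bone_params(), mesh_resolution=1.0)


@pytest.fixture(scope="session")
def bone_left():
    return generate_bone(calibrated_bone_params(side="L"), mesh_resolution=1.0)


@pytest.fixture(scope="session")
def icosphere():
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170309)


@pytest.fixture(scope="session")
def population_bundle():
    """One mid-size pipeline run shared by the end-to-end checks.

    40 specimens (10 per gender x side cell), higher left-side latent
    variance, coarse meshes to keep the run fast; classification is exercised
    separately on planted features.
    """
    config = PipelineConfig(
        population=PopulationConfig(
            n_per_group=10, seed=42, mesh_resolution=1.5, side_variance_ratio=3.0
        ),
        n_landmarks=300,
        icp_max_iter=25,
        icp_sample=1200,
        n_iterations=2,
        run_classification=False,
    )
    return run_pipeline(config)
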