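import numpy as np
import pytest

import hetmap
from hetmap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_config():
    return hetmap.FixtureConfig(seed=7)


@pytest.fixture(scope="session")
def default_stack(default_config):
    """Default 4-section 256x256 stack with true landmarks attached to every
    section (so the pipeline can evaluate itself against ground truth)."""
    stack = hetmap.make_stack(default_config)
    for sec, truth in zip(stack.sections, stack.ground_truth):
        sec.landmarks = truth.landmarks
    return stack


@pytest.fixture(scope="session")
def pipeline_result(default_stack):
    """Full pipeline run on the default stack; shared across tests because
    registration of three section pairs takes tens of seconds."""
    return run_pipeline(PipelineConfig(), default_stack.sections)


@pytest.fixture(scope="session")
def rigid_only_stack():
    """Two sections related by a pure rigid motion (no warp, no artifacts)."""
    cfg = hetmap.FixtureConfig(canvas_size=(192, 192), n_sections=2,
                               warp_amplitude=0.0, rigid_range=(15.0, 25.0),
                               artifact_rates={}, seed=5)
    return hetmap.make_stack(cfg)


@pytest.fixture(scope="session")
def aligned_pair():
    """Two renderings of the same undeformed tissue (different stains)."""
    cfg = hetmap.FixtureConfig(canvas_size=(192, 192), n_sections=2,
                               warp_amplitude=0.0, rigid_range=(0.0, 0.0),
                               artifact_rates={}, seed=11)
    return hetmap.make_stack(cfg)


@pytest.fixture(scope="session")
def demons_run(rigid_only_stack):
    """Pre-alignment + demons on a rigid-only pair: (fixed mask, aligned
    moving mask, demons field)."""
    from hetmap.global_reg import register_demons, warp_affine
    from hetmap.masking import rough_mask
    from hetmap.prealign import prealign

    stack = rigid_only_stack
    fm = rough_mask(stack.fixed)
    mm = rough_mask(stack.sections[1])
    rigid = prealign(fm, mm)
    aligned = warp_affine(mm, rigid.backward())
    field = register_demons(fm, aligned)
    return fm, aligned, field


@pytest.fixture
def rng():
    return np.random.default_rng(0)
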