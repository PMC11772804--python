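import numpy as np
import pytest

from cytoquant import (
    TissueSpec,
    generate_epithelium_stack,
    locate_nuclei_3d,
    local_projection,
)


def small_spec(**overrides) -> TissueSpec:
    """A fast-to-render tissue for property tests (not the study conditions)."""
    base = dict(
        field_size_px=(96, 96),
        n_planes=8,
        n_cells_target=25,
        curvature_sag_um=2.0,
        seed=0,
    )
    base.update(overrides)
    return TissueSpec(**base)


@pytest.fixture(scope="session")
def tissue_f10():
    """Default-conditions tissue with 10% binucleated cells, plus its
    projection — shared across segmentation tests (expensive to build)."""
    spec = TissueSpec(multinucleation_fraction=0.10, seed=1)
    stack, truth = generate_epithelium_stack(spec)
    anchors = locate_nuclei_3d(stack)
    proj = local_projection(stack, anchors)
    return spec, stack, truth, anchors, proj


@pytest.fixture(scope="session")
def domed_stack():
    """Noise-free tissue on a steep dome (sag spans 8 z-planes): the fixture
    on which curvature-aware projection must beat a fixed mid-stack one."""
    spec = TissueSpec(
        curvature_sag_um=8.0,
        n_planes=12,
        poisson_scale=0.0,
        gaussian_sd=0.0,
        seed=3,
    )
    stack, truth = generate_epithelium_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
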