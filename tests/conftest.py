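import numpy as np
import pytest

from vdrdti.behavior import RecallRecord, StudyDesign
from vdrdti.phantom import (
    GradientTable,
    PhantomLayout,
    SubjectPhantomParams,
    build_phantom,
    make_gradient_table,
)


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def gtab() -> GradientTable:
    """Default 64-direction, b=1000 scheme plus one b0."""
    return make_gradient_table(rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def gtab_small() -> GradientTable:
    """Cheap 12-direction scheme for phantom-level tests."""
    return make_gradient_table(n_dirs=12, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def noise_free_phantom(gtab_small):
    """One noise-free default phantom shared across tests."""
    layout = PhantomLayout(noise_sd=0.0)
    params = SubjectPhantomParams(uf_fa=0.65, control_fa=0.5, st_dispersion=0.05)
    dwi, fa_truth, masks, fibers = build_phantom(
        layout, params, gtab_small, np.random.default_rng(1)
    )
    return layout, params, dwi, fa_truth, masks, fibers


def worked_example_record(design: StudyDesign) -> RecallRecord:
    """The standard list with exactly four recalled words valued 12, 10, 11, 12."""
    values = design.list_values()
    recalled = np.zeros(design.words_per_list, bool)
    recalled[np.flatnonzero(values == 12)[:2]] = True
    recalled[np.flatnonzero(values == 11)[0]] = True
    recalled[np.flatnonzero(values == 10)[0]] = True
    return RecallRecord(values, recalled)
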