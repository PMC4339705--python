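"""Shared fixtures: synthetic study data and (expensive) matrix runs.

The heavyweight fixtures are session-scoped and lazily built, so a test
selection that does not need a full registration matrix never pays for
one.
"""

import numpy as np
import pytest

from doseacc.pipeline import StudyConfig, enumerate_methods, phantom_study, run_study
from doseacc.synthetic_phantom import PhantomSpec

SEED = 1  # fixed study seed for every seeded check


@pytest.fixture(scope="session")
def nc_spec():
    """Phantom without the contrast agent (registration-condition control)."""
    return PhantomSpec(seed=SEED, contrast_offset_hu=0.0, parotid_contrast_offset_hu=0.0)


@pytest.fixture(scope="session")
def nc_study(nc_spec):
    return phantom_study(nc_spec)


@pytest.fixture(scope="session")
def ct_study():
    """Phantom with planning-only contrast enhancement (the default course)."""
    return phantom_study(PhantomSpec(seed=SEED))


@pytest.fixture(scope="session")
def week6_pre_error(nc_study):
    """Mean landmark displacement at week 6 before any registration."""
    d = nc_study.weekly_landmarks[5].positions - nc_study.planning_landmarks.positions
    return float(np.linalg.norm(d, axis=1).mean())


@pytest.fixture(scope="session")
def report_nc(nc_study):
    """Full 11-method matrix run on the no-contrast course, final week."""
    return run_study(nc_study, config=StudyConfig(weeks=[6]))


@pytest.fixture(scope="session")
def report_ct(ct_study):
    """CT-input methods (no delineation maps) on the contrast course."""
    methods = [m for m in enumerate_methods() if m.input_mode != "dmaps"]
    return run_study(ct_study, methods=methods, config=StudyConfig(weeks=[6]), compare=False)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
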