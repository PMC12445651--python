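import numpy as np
import pytest

from iganpt.io import load_coefficients
from iganpt.risk_engine import CohortRecord


@pytest.fixture(scope="session")
def toy_coeffs():
    return load_coefficients("toy")


@pytest.fixture
def make_record():
    """Factory for CohortRecord with sensible defaults, overridable per test."""

    def _make(**kwargs):
        defaults = dict(
            patient_id="p0",
            age_years=22.0,
            sex="female",
            egfr=76.0,
            map_mmHg=99.0,
            proteinuria_g_day=1.4,
            mest_m=1,
            mest_e=0,
            mest_s=1,
            mest_t=0,
            race="chinese",
            rasb_use=False,
            is_use=False,
            novel_drugs=frozenset({"HCQ"}),
            followup_months=60.0,
            event=0,
        )
        defaults.update(kwargs)
        return CohortRecord(**defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
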