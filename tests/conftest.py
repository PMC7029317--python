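import numpy as np
import pytest
from hypothesis import settings

from abcds import load_fixture_profiles, load_subgroup_specs, simulate_cohort
from abcds.scale import PatientRecord

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_profiles():
    """Published per-subgroup summary profiles (all three strata)."""
    return load_fixture_profiles()


@pytest.fixture(scope="session")
def cdr1_cohort():
    """Seeded synthetic CDR-1 cohort (4 planted subgroups, n = 99)."""
    specs = load_subgroup_specs(stratum=1, dispersion_scale=0.5)
    return simulate_cohort(specs, seed=0)


def make_record(
    items=None, patient_id="p1", visit="baseline", cdr=1.0, cdr_sob=None, **aux
) -> PatientRecord:
    if items is None:
        items = (5,) * 13
    return PatientRecord(
        patient_id=patient_id,
        visit=visit,
        cdr=cdr,
        items=tuple(items),
        cdr_sob=cdr_sob,
        aux=aux,
    )


def row_from_items(items, patient_id="p1", visit="baseline", cdr=1, **extra):
    row = {"patient_id": patient_id, "visit": visit, "cdr": cdr}
    row.update({f"q{i + 1}": v for i, v in enumerate(items)})
    row.update(extra)
    return row
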