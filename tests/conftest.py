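import warnings

import pytest

from qmus.cohort import (
    CohortTable,
    Group,
    MuscleId,
    Sex,
    Side,
    SubjectRecord,
)
from qmus.reference import build_reference
from qmus.simulate import default_config, simulate_cohort


def make_record(
    subject_id="S1",
    group=Group.CONTROL,
    age=50.0,
    sex=Sex.F,
    relaxed=None,
    contracted=None,
    fasc=None,
    mrc=None,
    **kwargs,
):
    """Minimal valid subject with optional per-muscle observations."""
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=age,
        sex=sex,
        side=Side.RIGHT,
        relaxed_thickness=relaxed or {},
        contracted_thickness=contracted or {},
        fasciculation_present=fasc or {},
        mrc=mrc,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def default_cohort():
    """The 245-subject cohort at the default generating parameters."""
    return simulate_cohort(default_config(seed=7))


@pytest.fixture(scope="session")
def control_table(default_cohort):
    return CohortTable(
        records=default_cohort.by_group(Group.CONTROL), provenance="controls"
    )


@pytest.fixture(scope="session")
def default_reference(control_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference(control_table)


@pytest.fixture
def full_record():
    """A subject with every observation present."""
    return make_record(
        subject_id="FULL-1",
        group=Group.ALS,
        age=63.0,
        sex=Sex.M,
        relaxed={m: 1.0 for m in MuscleId},
        contracted={
            MuscleId.BICEPS: 2.0,
            MuscleId.APB: 0.5,
            MuscleId.QUADRICEPS: 2.0,
            MuscleId.TIBIALIS_ANTERIOR: 2.0,
        },
        fasc={m: False for m in MuscleId},
        mrc={"elbow_flex": 4.0, "bigtoe_ext": 3.0},
        disease_duration=2.0,
        clinical_scale_name="ALSFRS-R",
        clinical_scale_value=30.0,
    )
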