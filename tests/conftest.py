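import numpy as np
import pytest

from trisskit.registry import PatientRecord
from trisskit.scoring import ISS_REGIONS


def make_record(
    pid="p1",
    age=10,
    sex="male",
    mechanism="blunt",
    arrest=False,
    ais=None,
    gcs=15,
    sbp=120.0,
    rr=16.0,
    survived=True,
):
    """A complete, eligible record with overridable fields (None = missing)."""
    profile = {r: 0 for r in ISS_REGIONS}
    profile["head_neck"] = 3
    if ais is not None:
        profile = ais
    return PatientRecord(
        patient_id=pid,
        age_years=age,
        sex=sex,
        mechanism=mechanism,
        arrest_on_arrival=arrest,
        ais=profile,
        gcs_total=gcs,
        sbp_mmhg=sbp,
        rr_per_min=rr,
        survived=survived,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_registry_csv(tmp_path):
    """A 3-row well-formed registry CSV on disk."""
    path = tmp_path / "registry.csv"
    path.write_text(
        "patient_id,age_years,sex,mechanism,arrest_on_arrival,"
        "ais_head_neck,ais_face,ais_chest,ais_abdomen,ais_extremities,ais_external,"
        "gcs_total,sbp_mmhg,rr_per_min,survived\n"
        "a,4,male,blunt,0,3,0,0,0,0,0,15,110,20,1\n"
        "b,9,female,blunt,0,0,0,4,0,2,0,14,95,24,1\n"
        "c,16,male,blunt,0,5,0,3,2,0,0,6,70,35,0\n"
    )
    return path
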