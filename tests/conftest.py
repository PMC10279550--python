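import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from protraj.preprocess import filter_aptamers, log_zscore, select_samples
from protraj.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients x 40 proteins, default 4-subphenotype conditions."""
    return generate_cohort(default_config(n_patients=120, n_proteins=40, seed=11))


@pytest.fixture(scope="session")
def small_smatrix(small_cohort):
    filt = filter_aptamers(small_cohort.annotation)
    selected = select_samples(small_cohort.long, small_cohort.outcomes)
    return log_zscore(selected, retained=filt.retained)


@pytest.fixture()
def six_aptamer_annotation():
    """The canonical six-reagent filter fixture."""
    return pd.DataFrame(
        {
            "seq_id": ["A1", "A2", "A3", "A4", "A5", "A6"],
            "target_id": ["P1", "P1", "P2", "P3", "P4", "P5"],
            "is_human": [True, True, False, True, True, True],
            "is_validated": [True, True, True, False, True, True],
            "affinity_kd": [1.0, 5.0, 1.0, 1.0, 2.0, 9.0],
        }
    )


def tiny_long_table():
    """2 patients x 2 proteins x 2 visits."""
    rows = []
    for pid, times in [("P1", [0.0, 0.5]), ("P2", [0.0, 0.4])]:
        for v, t in enumerate(times):
            for j, sq in enumerate(["SQ1", "SQ2"]):
                rows.append((pid, f"{pid}-V{v}", t, sq, 100.0 * (j + 1) + 10 * v))
    return pd.DataFrame(rows, columns=["patient_id", "sample_id", "time_years",
                                       "seq_id", "rfu"])


@pytest.fixture()
def tiny_long():
    return tiny_long_table()


ADAT_FIXTURE = """^HEADER
!AdatId\tSYNTHETIC-0001
^COL_DATA
!Name\tSeqId\tTargetId\tIsHuman\tIsValidated\tAffinityKd
^ROW_DATA
!Name\tPatientId\tSampleId\tTimeYears
^TABLE_BEGIN
\t\t\tSeqId\tSQ1\tSQ2\tSQ3\tSQ4
\t\t\tTargetId\tT1\tT2\tT3\tT4
\t\t\tIsHuman\t1\t1\t1\t1
\t\t\tIsValidated\t1\t1\t1\t1
\t\t\tAffinityKd\t1.5\t2.5\t0.5\t1.0
PatientId\tSampleId\tTimeYears
P1\tP1-V00\t0.0\t100\t200\t300\t400
P1\tP1-V01\t0.5\t110\t210\t310\t410
P2\tP2-V00\t0.0\t120\t220\t320\t420
"""


@pytest.fixture()
def adat_file(tmp_path):
    path = tmp_path / "fixture.adat"
    path.write_text(ADAT_FIXTURE)
    return path
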