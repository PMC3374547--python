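import numpy as np
import pandas as pd
import pytest

from claimsdeid import build_default_hierarchies
from claimsdeid.synthetic_data import SynthConfig, generate_population, sample_dataset


@pytest.fixture(scope="session")
def hierarchies():
    return build_default_hierarchies()


@pytest.fixture(scope="session")
def population():
    """Mid-sized synthetic member population shared across tests."""
    return generate_population(
        SynthConfig(n_patients=120, seed=11, chronic_fraction=0.4)
    )


@pytest.fixture(scope="session")
def sample(population):
    return sample_dataset(population, 0.25, seed=12)


@pytest.fixture()
def tiny_csvs(tmp_path):
    """2-patient, 3-claim fixture in the release CSV layout."""
    patients = tmp_path / "patients.csv"
    claims = tmp_path / "claims.csv"
    patients.write_text(
        "MemberID,Age,Sex,DaysInHospital Y2,DaysInHospital Y3\n"
        "A1,34,F,0,2\n"
        "A2,71,M,5,0\n"
    )
    claims.write_text(
        "MemberID,ProviderID,Vendor,PCP,Year,Specialty,PlaceOfService,"
        "CPTCode,LOS,DSFC,PayDelay,Diagnosis\n"
        "A1,P1,V1,C1,Y1,Internal,Office,99213,0,0,30,250.00\n"
        "A1,P2,V1,C1,Y2,Surgery,InpatientHospital,27447,4,0,55,715.90\n"
        "A2,,V2,C2,Y1,Internal,Office,99214,0,0,21,401.9\n"
    )
    return patients, claims
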