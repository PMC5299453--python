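import numpy as np
import pandas as pd
import pytest

from rxdyn import EmrSnapshot, GeneratorConfig, generate_snapshot


def _d(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture(scope="session")
def small_snapshot() -> EmrSnapshot:
    """A modest synthetic snapshot shared across read-only tests."""
    cfg = GeneratorConfig(n_patients=300, n_providers=60, seed=42,
                          doc_length_mean=60.0)
    return generate_snapshot(cfg)


@pytest.fixture()
def hand_emr() -> EmrSnapshot:
    """Hand-crafted EMR with one qualifying patient and three decoys.

    A qualifies (coded indication, first-ever script, continued use);
    B has a prior zolpidem script long before the indicated index;
    C lacks a follow-up script; D has no insomnia indication at all.
    """
    patients = pd.DataFrame({
        "patient_id": ["A", "B", "C", "D"],
        "birth_date": [_d("1950-03-01")] * 4,
        "sex": ["F", "M", "F", "M"],
    })
    providers = pd.DataFrame({"provider_id": ["P1", "P2"]})
    diagnoses = pd.DataFrame({
        "patient_id": ["A", "B"],
        "date": [_d("2008-01-10"), _d("2008-01-15")],
        "icd9_code": ["780.52", "307.41"],
    })
    prescriptions = pd.DataFrame({
        "patient_id": ["A", "A", "B", "B", "B", "C", "D", "D"],
        "provider_id": ["P1", "P1", "P2", "P2", "P2", "P1", "P2", "P2"],
        "drug_name": ["trazodone", "trazodone", "zolpidem", "zolpidem",
                      "zolpidem", "trazodone", "zolpidem", "zolpidem"],
        "date": [_d("2008-06-01"), _d("2008-09-01"), _d("2007-01-01"),
                 _d("2008-06-01"), _d("2008-08-01"), _d("2008-06-01"),
                 _d("2008-06-01"), _d("2008-07-15")],
    })
    notes = pd.DataFrame({
        "note_id": ["N1", "N2"],
        "patient_id": ["C", "A"],
        "provider_id": ["P1", "P1"],
        "date": [_d("2008-02-01"), _d("2008-06-03")],
        "text": ["patient reports she sleeps   POORLY most nights",
                 "routine follow up, mood stable, discussed diet"],
    })
    return EmrSnapshot(patients, providers, diagnoses, prescriptions, notes)
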