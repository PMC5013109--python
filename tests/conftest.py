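import numpy as np
import pandas as pd
import pytest

from grace_recal.nomogram import Nomogram, PointTable
from grace_recal.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def tiny_nomogram() -> Nomogram:
    """A small hand-written nomogram whose scores are trivial to verify."""
    return Nomogram(
        continuous={
            "age": PointTable(breakpoints=(40.0, 60.0, 80.0), points=(0.0, 10.0, 20.0)),
            "heart_rate": PointTable(breakpoints=(50.0, 100.0), points=(0.0, 5.0)),
            "systolic_bp": PointTable(breakpoints=(80.0, 120.0, 160.0), points=(8.0, 4.0, 0.0)),
            "creatinine": PointTable(breakpoints=(50.0, 150.0), points=(0.0, 6.0)),
        },
        boolean_points={
            "diuretic_in_hospital": 7.0,
            "cardiac_arrest": 15.0,
            "st_deviation": 3.0,
            "elevated_markers": 2.0,
        },
        score_to_risk_curve=((0.0, 0.01), (20.0, 0.03), (40.0, 0.10), (60.0, 0.30)),
        name="tiny-test",
    )


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a typed cohort frame from partial row dicts (sensible defaults)."""
    defaults = dict(
        age=65.0, heart_rate=80.0, systolic_bp=140.0, creatinine=100.0,
        diuretic_in_hospital=False, cardiac_arrest=False, st_deviation=True,
        elevated_markers=True, oad_indicator=False, smoking="never",
        diagnosis="NSTEMI", diabetes=False, admission_year=2010, died_6m=False,
    )
    full = []
    for i, row in enumerate(rows):
        rec = {"patient_id": f"p{i}", **defaults, **row}
        full.append(rec)
    df = pd.DataFrame(full)
    for col in ("diuretic_in_hospital", "cardiac_arrest", "st_deviation",
                "elevated_markers", "oad_indicator", "diabetes", "died_6m"):
        df[col] = df[col].astype("boolean")
    df["smoking"] = df["smoking"].astype("string")
    df["diagnosis"] = df["diagnosis"].astype("string")
    df["admission_year"] = df["admission_year"].astype("Int64")
    return df


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """One shared 20k synthetic cohort for tests that need realistic structure."""
    return generate_cohort(GeneratorConfig(n=20_000, seed=2024))
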