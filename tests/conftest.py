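import pandas as pd
import pytest

from tscgp.annotation import get_reference
from tscgp.datasets import example_cohort, published_prevalences, published_tables


@pytest.fixture(scope="session")
def tsc1():
    return get_reference("TSC1")


@pytest.fixture(scope="session")
def tsc2():
    return get_reference("TSC2")


@pytest.fixture(scope="session")
def tables():
    return published_tables()


@pytest.fixture(scope="session")
def prevalences():
    return published_prevalences()


@pytest.fixture(scope="session")
def cohort():
    return example_cohort()


@pytest.fixture()
def cohort_csv(tmp_path, cohort):
    """The example cohort written out in the standard CSV schema."""
    df = pd.DataFrame([{
        "patient_id": r.patient_id, "gene": r.gene, "transcript": r.transcript or "",
        "hgvs_c": r.hgvs_c, "hgvs_p": r.hgvs_p or "", "sex": r.sex,
        "raml": int(r.raml), "source": r.source or "",
    } for r in cohort])
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path


def assert_printed(value, printed: str):
    """Assert a computed value matches a figure at its printed precision
    (within one unit in the last printed decimal place, since the source's
    own rounding of repeated quantities is inconsistent at the last digit)."""
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    assert abs(value - float(printed)) <= 10 ** -decimals + 1e-12, \
        f"{value} does not match printed {printed} at its precision"
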