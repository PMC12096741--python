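import numpy as np
import pandas as pd
import pytest

from pahkit.species import SPECIES_ORDER, default_catalog
from pahkit.data_model import SampleRecord
from pahkit.synthetic import SyntheticSpec, generate_samples


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_record(date="2019-01-05", site="A", pm25=40.0, temp=None,
                pressure=None, rh=None, **conc):
    """A SampleRecord with all species at 1.0 unless overridden."""
    c = {code: 1.0 for code in SPECIES_ORDER}
    c.update(conc)
    return SampleRecord(date=pd.Timestamp(date), site=site, pm25=pm25,
                        conc=c, temp=temp, pressure=pressure, rh=rh)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_campaign():
    """150 noisy site-day records with stored ground truth (seed 1)."""
    spec = SyntheticSpec(n_days=75, n_sites=2, noise_cv=0.10,
                         censor=False, seed=1)
    records, g, f = generate_samples(spec)
    return spec, records, g, f


def sample_table(records):
    from pahkit.data_model import records_to_frame
    return records_to_frame(records)


@pytest.fixture
def sample_csv(tmp_path):
    """Write a minimal well-formed 3-row sample table; returns its path."""
    rows = []
    for i, (d, s) in enumerate([("2019-01-01", "A"), ("2019-01-02", "A"),
                                ("2019-01-03", "B")]):
        row = {"date": d, "site": s, "pm25": 30.0 + i}
        row.update({c: 1.0 + 0.1 * i for c in SPECIES_ORDER})
        rows.append(row)
    path = tmp_path / "samples.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
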