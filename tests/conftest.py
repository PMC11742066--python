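import datetime as dt

import numpy as np
import pytest

from hhosvr.data_io import CdcRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(values, countyfips=1001, statefips=1, start=dt.date(2003, 1, 1)):
    """County-day records with the given daily maxima, one day apart."""
    records = []
    for offset, v in enumerate(values):
        day = start + dt.timedelta(days=offset)
        records.append(
            CdcRecord(
                statefips=statefips,
                countyfips=countyfips,
                year=day.year,
                date=day,
                pm25_max_pred=float(v),
                pm25_med_pred=float(v) * 0.8,
                pm25_mean_pred=float(v) * 0.85,
                pm25_pop_pred=float(v) * 0.9,
            )
        )
    return records


@pytest.fixture
def small_cdc_csv(tmp_path):
    """Three well-formed rows in the canonical schema."""
    path = tmp_path / "pm25.csv"
    path.write_text(
        "STATEFIPS,COUNTYFIPS,YEAR,DATE,PM2.5-MAX-PRED,PM2.5-MED-PRED,"
        "PM2.5-MEAN-PRED,PM2.5-POP-PRED\n"
        "1,1001,2003,01-01-2003,12.5,10.1,10.4,10.8\n"
        "1,1001,2003,02-01-2003,14.2,11.0,11.5,11.9\n"
        "1,1003,2003,01-01-2003,9.8,8.0,8.3,8.6\n"
    )
    return path
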