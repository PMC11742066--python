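"""Packaged benchmark fixtures.

Ships the published per-run MAPE matrices of the eight metaheuristic-tuned
SVR variants on the five Alabama county PM2.5 datasets (FIPS 1001, 1003,
1005, 1007, 1009): 10 independent runs x 8 algorithms each.  These are
inputs for the Friedman ranking reproduction, not outputs of this package.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["COUNTIES", "ALGORITHMS", "load_mape_runs"]

COUNTIES = ("1001", "1003", "1005", "1007", "1009")
ALGORITHMS = ("EO", "GWO", "HGSO", "BMO", "MRFO", "SSA", "WOA", "HHO")


def load_mape_runs(county: str | int) -> pd.DataFrame:
    """10 x 8 per-run MAPE matrix of one county dataset (rows = runs)."""
    county = str(county)
    if county not in COUNTIES:
        raise ValueError(f"unknown county {county!r}; available: {COUNTIES}")
    resource = files("hhosvr").joinpath(f"data/mape_runs_{county}.csv")
    with resource.open("r") as fh:
        frame = pd.read_csv(fh)
    assert tuple(frame.columns) == ALGORITHMS and frame.shape == (10, 8)
    return frame
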