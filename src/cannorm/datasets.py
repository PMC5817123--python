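"""Packaged worked-example datasets.

``load_census_table`` returns the published 11-population census/distribution
table (the pooled Solitary pseudo-population ``sol`` plus tanks g1-g10) with
columns x1 (cannibals), x2 (victims), y1 (size-shape correlation), y2 (size
skewness), y3 (shape skewness).  The AIC tables carry the published
model-comparison AIC columns used to exercise the Akaike-weight arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .population_norm import PopulationSummary

__all__ = [
    "load_census_table",
    "census_table_summaries",
    "load_nonlinear_aic_table",
    "load_largest_cannibal_aic_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("cannorm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_census_table() -> pd.DataFrame:
    return _read("census_table.csv")


def census_table_summaries() -> list[PopulationSummary]:
    df = load_census_table()
    return [
        PopulationSummary(
            tank_id=row.tank_id, x1=int(row.x1), x2=int(row.x2),
            y1=float(row.y1), y2=float(row.y2), y3=float(row.y3),
        )
        for row in df.itertuples()
    ]


def load_nonlinear_aic_table() -> pd.DataFrame:
    return _read("nonlinear_model_aic.csv")


def load_largest_cannibal_aic_table() -> pd.DataFrame:
    return _read("largest_cannibal_aic.csv")
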