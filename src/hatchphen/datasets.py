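"""Bundled reference data.

``load_incubation_summary`` returns the laboratory split-brood incubation
summary: one row per treatment × fertilization date with the mean ± SD
incubation temperature (°C, fertilization to last hatch), ATU at 50% hatch
and days post fertilization at 50% hatch (mean ± SD across tubes).
Treatments: A = constant ~5.3 °C; B = warm spike to 10 °C in late
December/early January, then constant 3.4 °C; C = cold spike to 2 °C, then
constant 3.4 °C.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_incubation_summary"]


def load_incubation_summary() -> pd.DataFrame:
    path = resources.files("hatchphen") / "data" / "incubation_summary.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    df["fert_date"] = pd.to_datetime(df["fert_date"]).dt.date
    return df
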