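"""Bookkeeping for the study's plantation survey summary.

A survey of 144 Sabah plantations grouped under six mills, split across
three management types and two certification waves (2018 and 2023). The
printed per-type counts and areas are inputs; the derived totals and shares
are computed here so the arithmetic is checkable.
"""

from __future__ import annotations

import pandas as pd

#: Per-type plantation counts and areas (hectares) of the surveyed producer.
SURVEY_SUMMARY = pd.DataFrame(
    {
        "type": ["own_estate", "outside_supplier_estate", "small_grower"],
        "n_plantations": [28, 39, 77],
        "n_certified_2018": [5, 11, 32],
        "n_certified_2023": [23, 28, 45],
        "area_ha": [33026, 90469, 12188],
    }
)

STUDY_YEARS = (2017, 2018, 2019, 2020, 2021, 2022, 2023)


def total_plantations(summary: pd.DataFrame = SURVEY_SUMMARY) -> int:
    return int(summary["n_plantations"].sum())


def total_certified_area_ha(summary: pd.DataFrame = SURVEY_SUMMARY) -> int:
    """Total certified plantation area in hectares across all types."""
    return int(summary["area_ha"].sum())


def certified_2018_share_pct(summary: pd.DataFrame = SURVEY_SUMMARY) -> float:
    """Percentage of plantations certified in the 2018 wave."""
    return 100.0 * summary["n_certified_2018"].sum() / summary["n_plantations"].sum()


def own_estate_2018_share_pct(summary: pd.DataFrame = SURVEY_SUMMARY) -> float:
    """Percentage of own estates that certified in 2018."""
    own = summary.set_index("type").loc["own_estate"]
    return 100.0 * own["n_certified_2018"] / own["n_plantations"]
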