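"""Bundled reference datasets.

Currently one dataset: the published district-level illustration of
mobility-weighted cumulative NO2 exposure for the 20 arrondissements of
Paris (2006 census mobility, five-year latency window), used as a worked
example and as an arithmetic fixture for the reporting layer.
"""

from __future__ import annotations

import pandas as pd

# (arrondissement, degree of mobility %, cumulative exposure without
#  residential mobility, with residential mobility, relative difference);
# exposures in µg/m³, rows ranked by descending degree of mobility.
_PARIS_ROWS = [
    (15, 19.0, 44.23, 38.64, 5.59),
    (17, 18.5, 49.91, 44.00, 5.91),
    (14, 18.4, 42.17, 37.75, 4.42),
    (11, 18.4, 45.74, 41.14, 4.60),
    (10, 18.3, 48.15, 43.76, 4.39),
    (9, 17.1, 46.99, 43.32, 3.66),
    (16, 17.0, 46.10, 40.81, 5.29),
    (18, 16.5, 47.56, 42.89, 4.67),
    (5, 16.2, 44.60, 40.66, 3.94),
    (2, 15.8, 46.64, 43.51, 3.13),
    (3, 15.6, 49.10, 45.55, 3.55),
    (8, 15.4, 48.00, 44.46, 3.54),
    (7, 15.4, 44.60, 40.42, 4.18),
    (12, 15.3, 46.09, 42.30, 3.78),
    (13, 14.6, 41.07, 37.94, 3.13),
    (20, 14.1, 45.51, 42.46, 3.05),
    (6, 13.1, 45.84, 42.07, 3.77),
    (4, 12.7, 49.17, 45.67, 3.50),
    (19, 12.6, 45.91, 43.20, 2.71),
    (1, 8.8, 50.46, 47.34, 3.11),
]

PARIS_COLUMNS = [
    "degree_of_mobility",
    "cumulative_without_mobility",
    "cumulative_with_mobility",
    "relative_difference",
]


def paris_arrondissement_table() -> pd.DataFrame:
    """Five-year cumulative NO2 exposure for the 20 Paris arrondissements.

    Returns the published per-district values exactly as printed: degree of
    residential mobility (% of 2006 residents who lived in a different
    district five years earlier, movements outside the city ignored) and
    cumulative exposure with and without accounting for residential
    mobility, plus their difference. Rows are ranked by descending degree
    of mobility. Values carry two-decimal printed rounding.
    """
    df = pd.DataFrame(
        _PARIS_ROWS,
        columns=["arrondissement"] + PARIS_COLUMNS,
    ).set_index("arrondissement")
    return df
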