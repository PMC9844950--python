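"""Reference constants of the 17-country study configuration.

The packaged values are the study window (March 11, 2020 – September 22,
2022, 926 days) and, per ISO-3 country code, the number of first-level
administrative divisions used for stratification. Region polygons
themselves are not packaged (they are distributed as standard country
shapefiles/GeoJSON, e.g. via diva-gis); loading them with
:func:`mobimetrics.load_regions` against these expected division counts
is a cheap integrity check.
"""

import pandas as pd

STUDY_START = pd.Timestamp("2020-03-11")
STUDY_END = pd.Timestamp("2022-09-22")
STUDY_DAYS = 926

#: ISO-3 code -> number of first-level administrative divisions
FIRST_LEVEL_DIVISIONS = {
    "ARG": 24,
    "CHL": 16,
    "COL": 32,
    "CRI": 7,
    "ECU": 24,
    "GRC": 8,
    "GTM": 22,
    "ITA": 20,
    "MEX": 32,
    "NIC": 18,
    "PAN": 13,
    "PER": 26,
    "PHL": 81,
    "SVN": 14,
    "TUR": 81,
    "USA": 52,
    "VEN": 25,
}

STUDY_COUNTRIES = tuple(sorted(FIRST_LEVEL_DIVISIONS))


def check_region_count(region_set) -> bool:
    """True when a loaded RegionSet has the expected number of first-level
    divisions for its country (unknown countries pass trivially)."""
    expected = FIRST_LEVEL_DIVISIONS.get(region_set.country)
    return expected is None or region_set.C == expected
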