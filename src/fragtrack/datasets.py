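"""Bundled reference tables: published forest-cover and fragmentation
figures for the Chure Terai Madhesh Landscape (CTML), Nepal.

These are the printed area tables of a national 1930–2020 elephant
habitat assessment, bundled so the change-arithmetic layer can be
exercised and demonstrated on real published numbers without access to
the original (undeposited) raster maps.  Areas are km²; epochs are the
four survey years 1930, 1975, 2000 and 2020.
"""

from __future__ import annotations

import pandas as pd

CTML_YEARS = [1930, 1975, 2000, 2020]

#: Forest area (km²) per region and survey year.
CTML_FOREST_AREA_KM2: dict[str, dict[int, float]] = {
    "Eastern":     {1930: 4607.92, 1975: 4084.94, 2000: 3781.68, 2020: 3548.48},
    "Central":     {1930: 4336.84, 1975: 4162.02, 2000: 3917.77, 2020: 3771.95},
    "Western":     {1930: 6703.66, 1975: 5590.97, 2000: 5186.52, 2020: 4993.85},
    "Far-western": {1930: 8667.14, 1975: 7482.98, 2000: 7167.34, 2020: 6754.86},
    "Total":       {1930: 24315.56, 1975: 21320.92, 2000: 20053.32, 2020: 19069.14},
}

#: Fragmentation-class area (km²) of the whole landscape per survey year.
CTML_FRAG_CLASS_AREA_KM2: dict[str, dict[int, float]] = {
    "patch":      {1930: 0.16, 1975: 157.11, 2000: 165.69, 2020: 210.85},
    "edge":       {1930: 1086.55, 1975: 2825.61, 2000: 2910.84, 2020: 3279.62},
    "perforated": {1930: 0.67, 1975: 1876.53, 2000: 1430.23, 2020: 1693.21},
    "core1":      {1930: 42.18, 1975: 422.32, 2000: 474.32, 2020: 509.25},
    "core2":      {1930: 49.34, 1975: 157.51, 2000: 182.84, 2020: 207.65},
    "core3":      {1930: 23136.67, 1975: 15881.84, 2000: 14889.40, 2020: 13168.56},
}


def ctml_forest_areas() -> pd.DataFrame:
    """Region × year forest areas (km²), total row included."""
    return pd.DataFrame(CTML_FOREST_AREA_KM2).T[CTML_YEARS]


def ctml_class_areas() -> pd.DataFrame:
    """Fragmentation class × year areas (km²) for the whole landscape."""
    return pd.DataFrame(CTML_FRAG_CLASS_AREA_KM2).T[CTML_YEARS]
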