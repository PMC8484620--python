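"""Forest-change quantification between epochs.

Covers the change-detection arithmetic of a multi-decade habitat
assessment: per-pixel loss/gain maps, percent change and compound
annual rates of forest-area change, 5 km grid-cell summaries, class
cross-tabulations between fragmentation maps, regional report tables
and overlay of conflict-event points on change maps.

Sign convention: internal values are signed, loss negative.  The
compound annual rate follows the continuous-compounding formula

    r = 100 · ln(a2 / a1) / (t2 − t1)   [%/yr]

so areas ``a1, a2`` at years ``t1, t2`` satisfy ``a2 = a1·e^{rΔt/100}``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import (
    BinaryLandscape,
    GridSet,
    LandscapeSeries,
    PointSet,
    FOREST,
    require_aligned,
)
from .fragmentation import (
    CLASS_NAMES,
    FragParams,
    FragmentationMap,
    classify_fragmentation,
    class_area_summary,
)

# change-map codes
STABLE_NONFOREST = 0
LOSS = 1
GAIN = 2
STABLE_FOREST = 3
CHANGE_NAMES = {
    STABLE_NONFOREST: "stable_nonforest",
    LOSS: "loss",
    GAIN: "gain",
    STABLE_FOREST: "stable_forest",
}


@dataclass(frozen=True)
class ChangeMap:
    """Pixel-level transition map between two epochs."""

    values: np.ndarray
    t1: int
    t2: int
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local"

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.values), dtype=np.uint8)
        if v.ndim != 2 or v.max(initial=0) > STABLE_FOREST:
            raise ValueError("invalid change grid")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape

    @property
    def bounds(self):
        x0, y0 = self.origin
        nrow, ncol = self.shape
        return (x0, y0 - nrow * self.pixel_size, x0 + ncol * self.pixel_size, y0)

    def area_km2(self, code: int) -> float:
        return float((self.values == code).sum()) * self.pixel_size**2 / 1e6

    @property
    def loss_area_km2(self) -> float:
        return self.area_km2(LOSS)

    @property
    def gain_area_km2(self) -> float:
        return self.area_km2(GAIN)


# ---------------------------------------------------------------------------
# scalar change arithmetic
# ---------------------------------------------------------------------------

def percent_change(a1: float, a2: float) -> float:
    """Signed percent change 100·(a2 − a1)/a1; negative means loss."""
    if not a1 > 0:
        warnings.warn("percent change undefined for a1 <= 0; returning NaN")
        return math.nan
    return 100.0 * (a2 - a1) / a1


def annual_rate(a1: float, a2: float, t1: float, t2: float) -> float:
    """Compound annual rate of change, 100·ln(a2/a1)/(t2−t1) in %/yr."""
    if not t2 > t1:
        raise ValueError(f"t2 must exceed t1, got {t1} -> {t2}")
    if not a1 > 0:
        raise ValueError("a1 must be > 0")
    if a2 < 0:
        raise ValueError("a2 must be >= 0")
    if a2 == 0:
        warnings.warn("a2 = 0: annual rate diverges to -inf")
        return -math.inf
    return 100.0 * math.log(a2 / a1) / (t2 - t1)


def change_report_from_areas(
    areas: dict[int, float] | pd.Series, pairs: list[tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Percent-change and annual-rate table from a year→area mapping.

    By default reports every consecutive epoch pair plus (first, last).
    This is the pure arithmetic layer: it works directly on published
    area tables as well as on areas measured from rasters.
    """
    series = pd.Series(dict(areas)).sort_index()
    years = list(series.index)
    if len(years) < 2:
        raise ValueError("need at least two epochs")
    if pairs is None:
        pairs = list(zip(years, years[1:]))
        if (years[0], years[-1]) not in pairs:
            pairs.append((years[0], years[-1]))
    rows = []
    for y1, y2 in pairs:
        a1, a2 = float(series[y1]), float(series[y2])
        rows.append({
            "period": f"{y1}-{y2}",
            "t1": y1, "t2": y2,
            "area_t1_km2": a1, "area_t2_km2": a2,
            "change_km2": a2 - a1,
            "percent_change": percent_change(a1, a2),
            "annual_rate_pct": annual_rate(a1, a2, y1, y2),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raster change
# ---------------------------------------------------------------------------

def change_map(t1: BinaryLandscape, t2: BinaryLandscape) -> ChangeMap:
    """Per-pixel 2×2 change classification between two aligned epochs.

    nodata in either epoch is treated as non-forest, so
    ``loss_area + stable_forest_area`` equals the epoch-1 forest area
    exactly.
    """
    require_aligned(t1, t2)
    f1 = t1.forest_mask()
    f2 = t2.forest_mask()
    values = np.full(f1.shape, STABLE_NONFOREST, dtype=np.uint8)
    values[f1 & ~f2] = LOSS
    values[~f1 & f2] = GAIN
    values[f1 & f2] = STABLE_FOREST
    y1 = t1.epoch_year if t1.epoch_year is not None else 0
    y2 = t2.epoch_year if t2.epoch_year is not None else 1
    return ChangeMap(values, int(y1), int(y2), t1.pixel_size, t1.origin, t1.crs_id)


def _cell_index_grid(landscape: BinaryLandscape, grid: GridSet) -> np.ndarray:
    """Grid-cell id of every pixel, by pixel-centre membership (half-open
    cells anchored at the raster origin)."""
    nrow, ncol = landscape.shape
    ps, cs = landscape.pixel_size, grid.cell_size
    col_of = np.minimum(((np.arange(ncol) + 0.5) * ps / cs).astype(int), grid.n_cols - 1)
    row_of = np.minimum(((np.arange(nrow) + 0.5) * ps / cs).astype(int), grid.n_rows - 1)
    return row_of[:, None] * grid.n_cols + col_of[None, :] + 1


def grid_change_summary(series: LandscapeSeries, grid: GridSet) -> pd.DataFrame:
    """Forest area per grid cell per epoch, with first-to-last change.

    Columns: ``cell_id``, one ``area_<year>_km2`` per epoch,
    ``change_km2``, ``percent_change``, ``annual_rate_pct`` and
    ``category`` ∈ {complete_loss, deforested, gain, stable}; a cell
    that loses its entire forest is complete_loss (a strict subset of
    deforestation), categories are mutually exclusive.
    """
    first = series.first
    cell_ids = _cell_index_grid(first, grid)
    n_cells = grid.n_cols * grid.n_rows
    pixel_km2 = first.pixel_size**2 / 1e6
    data: dict[str, np.ndarray] = {"cell_id": np.arange(1, n_cells + 1)}
    area_cols = []
    for epoch in series:
        counts = np.bincount(cell_ids[epoch.forest_mask()], minlength=n_cells + 1)[1:]
        col = f"area_{epoch.epoch_year}_km2"
        data[col] = counts * pixel_km2
        area_cols.append(col)
    df = pd.DataFrame(data)
    a1 = df[area_cols[0]].to_numpy()
    a2 = df[area_cols[-1]].to_numpy()
    y1, y2 = series.years[0], series.years[-1]
    df["change_km2"] = a2 - a1
    with np.errstate(divide="ignore", invalid="ignore"):
        df["percent_change"] = np.where(a1 > 0, 100.0 * (a2 - a1) / np.where(a1 > 0, a1, 1), np.nan)
        rate = np.where((a1 > 0) & (a2 > 0),
                        100.0 * np.log(np.where(a2 > 0, a2, 1) / np.where(a1 > 0, a1, 1)) / (y2 - y1),
                        np.nan)
        rate = np.where((a1 > 0) & (a2 == 0), -np.inf, rate)
    df["annual_rate_pct"] = rate
    category = np.full(n_cells, "stable", dtype=object)
    category[a2 < a1] = "deforested"
    category[(a1 > 0) & (a2 == 0)] = "complete_loss"
    category[a2 > a1] = "gain"
    df["category"] = category
    return df


def crosstab(m1: FragmentationMap, m2: FragmentationMap) -> pd.DataFrame:
    """Class-by-class area cross-tabulation (km²) between two
    fragmentation maps; rows are epoch-1 classes, columns epoch-2.

    Marginals reproduce the per-epoch class-area summaries exactly.
    """
    if m1.shape != m2.shape or m1.pixel_size != m2.pixel_size:
        raise ValueError("fragmentation maps are not aligned")
    if m1.params != m2.params:
        raise ValueError("fragmentation maps were produced with different parameters")
    combined = m1.classes.astype(np.int32) * 7 + m2.classes
    counts = np.bincount(combined.ravel(), minlength=49).reshape(7, 7)
    areas = counts * (m1.pixel_size**2 / 1e6)
    names = [CLASS_NAMES[c] for c in range(7)]
    return pd.DataFrame(areas, index=pd.Index(names, name=f"t{m1.epoch_year or 1}"),
                        columns=pd.Index(names, name=f"t{m2.epoch_year or 2}"))


def points_in_loss(points: PointSet, change: ChangeMap) -> tuple[float, pd.DataFrame]:
    """Fraction of in-extent points whose containing pixel is a loss
    pixel, plus per-point labels.

    Points outside the raster extent are excluded from the fraction but
    reported (``inside`` column False), never silently dropped.
    """
    xmin, ymin, xmax, ymax = change.bounds
    inside = (points.x >= xmin) & (points.x < xmax) & (points.y > ymin) & (points.y <= ymax)
    if not inside.any():
        raise ValueError("no points fall inside the raster extent")
    col = np.clip(((points.x - xmin) / change.pixel_size).astype(int), 0, change.shape[1] - 1)
    row = np.clip(((ymax - points.y) / change.pixel_size).astype(int), 0, change.shape[0] - 1)
    is_loss = (change.values[row, col] == LOSS) & inside
    labels = pd.DataFrame({
        "x": points.x, "y": points.y,
        "inside": inside,
        "in_loss": is_loss,
        "change_class": [CHANGE_NAMES[c] for c in change.values[row, col]],
    })
    labels.loc[~inside, "change_class"] = "outside_extent"
    fraction = float(is_loss.sum() / inside.sum())
    return fraction, labels


# ---------------------------------------------------------------------------
# regional reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionalReport:
    """Tabular mirror of a regional habitat-change assessment.

    ``forest_area``: region × epoch forest areas (km²) with a total row
    and per-epoch share-of-total columns; ``change``: percent change and
    annual rate per region per epoch pair; ``class_area``: fragmentation
    class × epoch areas per region; ``class_change``: per-class change
    over the full period per region.
    """

    forest_area: pd.DataFrame
    change: pd.DataFrame
    class_area: dict[str, pd.DataFrame]
    class_change: pd.DataFrame


def _region_masks(landscape: BinaryLandscape, regions) -> dict[str, np.ndarray]:
    """Pixel-centre rasterisation of named regions (or a GridSet)."""
    import shapely

    if isinstance(regions, GridSet):
        named = [(f"cell_{cid}", poly) for cid, poly in regions.cells]
    else:
        named = list(regions)
    xs, ys = landscape.pixel_centers()
    xx, yy = np.meshgrid(xs, ys)
    masks = {}
    for name, poly in named:
        shapely.prepare(poly)
        masks[str(name)] = shapely.contains_xy(poly, xx, yy)
    return masks


def regional_report(
    series: LandscapeSeries,
    regions,
    params: FragParams | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> RegionalReport:
    """Forest-area, change-rate and fragmentation-class tables per region.

    ``regions`` is a list of ``(name, shapely polygon)`` pairs (or a
    GridSet).  Fragmentation is classified once per epoch on the full
    landscape, then tabulated within each region mask, so region
    boundaries never create artificial forest edges.
    """
    params = params or FragParams()
    masks = _region_masks(series.first, regions)
    years = series.years
    pixel_km2 = series.first.pixel_size**2 / 1e6

    fmaps = {e.epoch_year: classify_fragmentation(e, params) for e in series}

    area = {
        name: [float((e.forest_mask() & m).sum()) * pixel_km2 for e in series]
        for name, m in masks.items()
    }
    fa = pd.DataFrame(area, index=pd.Index(years, name="year")).T
    fa.loc["Total"] = fa.sum(axis=0)
    for y in years:
        fa[f"share_{y}_pct"] = 100.0 * fa[y] / fa.loc["Total", y]

    change_rows = []
    for name in list(masks) + ["Total"]:
        series_areas = {y: fa.loc[name, y] for y in years}
        tab = change_report_from_areas(series_areas, pairs)
        tab.insert(0, "region", name)
        change_rows.append(tab)
    change = pd.concat(change_rows, ignore_index=True)

    forest_classes = [CLASS_NAMES[c] for c in range(1, 7)]
    class_area: dict[str, pd.DataFrame] = {}
    for name, m in masks.items():
        rows = {}
        for y in years:
            cls = fmaps[y].classes
            counts = np.bincount(cls[m], minlength=7)
            rows[y] = counts[1:] * pixel_km2
        class_area[name] = pd.DataFrame(rows, index=pd.Index(forest_classes, name="class"))

    cc_rows = []
    y1, y2 = years[0], years[-1]
    for name, tab in class_area.items():
        for cname in forest_classes:
            a1, a2 = float(tab.loc[cname, y1]), float(tab.loc[cname, y2])
            cc_rows.append({
                "region": name, "class": cname,
                f"area_{y1}_km2": a1, f"area_{y2}_km2": a2,
                "change_km2": a2 - a1,
                "percent_change": percent_change(a1, a2) if a1 > 0 else math.nan,
            })
    class_change = pd.DataFrame(cc_rows)
    return RegionalReport(fa, change, class_area, class_change)
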