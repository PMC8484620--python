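"""Pixel-level forest fragmentation classification.

Every forest pixel is assigned to exactly one of six fragmentation
classes — patch, edge, perforated, core 1, core 2, core 3 — following
the landscape-fragmentation-tool family of definitions:

* **core** pixels lie farther than the edge width (default 100 m) from
  any non-forest pixel; contiguous core tracts are split into three
  size classes at 250 and 500 acres;
* **perforated** (inner-edge) pixels are non-core forest whose nearest
  non-forest pixel belongs to an interior opening (a "hole" fully
  enclosed by forest);
* **edge** (outer-edge) pixels are non-core forest adjacent to exterior
  non-forest;
* **patch** pixels belong to forest fragments too small or thin to
  contain any core.

Distances are centre-to-centre Euclidean, computed with an exact
distance transform.  With 30 m pixels, "> 100 m" therefore means at
least four pixels orthogonally.  Ties between a hole and exterior
non-forest at exactly equal distance resolve to edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .landscape import (
    BinaryLandscape,
    FOREST,
    connectivity_structure,
)

#: square metres per acre (international acre)
ACRE_M2 = 4046.8564224
#: exact conversions of the core-size thresholds
ACRES_250_KM2 = 250 * ACRE_M2 / 1e6   # 1.0117141056 km²
ACRES_500_KM2 = 500 * ACRE_M2 / 1e6   # 2.0234282112 km²

# fragmentation class codes (stable; written to class rasters)
CLASS_NONFOREST = 0
CLASS_PATCH = 1
CLASS_EDGE = 2
CLASS_PERFORATED = 3
CLASS_CORE1 = 4
CLASS_CORE2 = 5
CLASS_CORE3 = 6

CLASS_NAMES: dict[int, str] = {
    CLASS_NONFOREST: "nonforest",
    CLASS_PATCH: "patch",
    CLASS_EDGE: "edge",
    CLASS_PERFORATED: "perforated",
    CLASS_CORE1: "core1",
    CLASS_CORE2: "core2",
    CLASS_CORE3: "core3",
}
FOREST_CLASSES = (CLASS_PATCH, CLASS_EDGE, CLASS_PERFORATED,
                  CLASS_CORE1, CLASS_CORE2, CLASS_CORE3)


@dataclass(frozen=True)
class FragParams:
    """Parameters of the fragmentation model.

    Attributes
    ----------
    edge_width
        Buffer distance (m) separating core from peripheral forest.
    core_small_max, core_medium_max
        Core-tract area thresholds in km².  Defaults are the exact
        conversions of 250 and 500 acres; ``core2`` is the closed
        interval ``[core_small_max, core_medium_max]``.
    boundary_policy
        Whether the world outside the raster counts as non-forest
        (``outside_is_nonforest``, default) or forest.
    forest_connectivity, hole_connectivity
        Pixel connectivity for forest components (8) and for interior
        openings (4) — the standard dual pair.
    max_hole_area
        Openings larger than this (km²) are treated as exterior
        non-forest rather than perforations; ``inf`` = unlimited.
    """

    edge_width: float = 100.0
    core_small_max: float = ACRES_250_KM2
    core_medium_max: float = ACRES_500_KM2
    boundary_policy: str = "outside_is_nonforest"
    forest_connectivity: int = 8
    hole_connectivity: int = 4
    max_hole_area: float = math.inf
    nodata_as: str = "nonforest"

    def __post_init__(self) -> None:
        if not (0 < self.core_small_max < self.core_medium_max):
            raise ValueError(
                "core thresholds must satisfy 0 < core_small_max < core_medium_max; "
                f"got {self.core_small_max}, {self.core_medium_max}"
            )
        if self.edge_width < 0:
            raise ValueError("edge_width must be >= 0")
        if self.boundary_policy not in ("outside_is_nonforest", "outside_is_forest"):
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")
        connectivity_structure(self.forest_connectivity)
        connectivity_structure(self.hole_connectivity)
        if self.max_hole_area <= 0:
            raise ValueError("max_hole_area must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["max_hole_area"] = None if math.isinf(self.max_hole_area) else self.max_hole_area
        return d


@dataclass(frozen=True)
class FragmentationMap:
    """Per-pixel fragmentation class raster plus its provenance."""

    classes: np.ndarray
    params: FragParams
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "local"
    epoch_year: int | None = None

    def __post_init__(self) -> None:
        c = np.ascontiguousarray(np.asarray(self.classes), dtype=np.uint8)
        if c.ndim != 2:
            raise ValueError("classes must be a 2-D grid")
        if c.max(initial=0) > CLASS_CORE3:
            raise ValueError("invalid class code in grid")
        object.__setattr__(self, "classes", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def pixel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.classes.ravel(), minlength=7)
        return {CLASS_NAMES[code]: int(counts[code]) for code in range(7)}

    def summary(self) -> "ClassAreaTable":
        return class_area_summary(self)


@dataclass(frozen=True)
class ClassAreaTable:
    """Area (km²) of each fragmentation class for one epoch."""

    areas_km2: dict[str, float]
    pixel_counts: dict[str, int]
    epoch_year: int | None = None

    @property
    def total_forest_km2(self) -> float:
        return sum(v for k, v in self.areas_km2.items() if k != "nonforest")

    def to_frame(self):
        import pandas as pd

        classes = [CLASS_NAMES[c] for c in FOREST_CLASSES]
        return pd.DataFrame(
            {
                "class": classes,
                "pixels": [self.pixel_counts[c] for c in classes],
                "area_km2": [self.areas_km2[c] for c in classes],
            }
        )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def label_components(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a boolean grid.

    Returns ``(labels, areas)`` where labels run 1..K in row-major order
    of each component's first pixel and ``areas[k]`` is the pixel count
    of component ``k`` (``areas[0]`` is the background count).
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool),
                              structure=connectivity_structure(connectivity))
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    return labels, areas


def distance_to_nonforest(
    landscape: BinaryLandscape, params: FragParams | None = None
) -> np.ndarray:
    """Euclidean centre-to-centre distance (m) from every pixel to the
    nearest non-forest pixel.

    Non-forest pixels have distance 0.  Under ``outside_is_nonforest`` a
    virtual ring of non-forest borders the grid; under
    ``outside_is_forest`` an all-forest grid yields ``+inf``.
    """
    params = params or FragParams()
    forest = landscape.forest_mask(params.nodata_as)
    if params.boundary_policy == "outside_is_nonforest":
        padded = np.pad(forest, 1, constant_values=False)
        d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    else:
        if forest.all():
            return np.full(forest.shape, np.inf)
        d = ndimage.distance_transform_edt(forest)
    return d * landscape.pixel_size


def _hole_mask(nonforest: np.ndarray, params: FragParams, pixel_area_km2: float) -> np.ndarray:
    """Interior openings: non-forest components (hole connectivity) that
    do not touch the grid boundary and are no larger than max_hole_area."""
    labels, areas = label_components(nonforest, params.hole_connectivity)
    if labels.max() == 0:
        return np.zeros_like(nonforest, dtype=bool)
    touching = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    is_hole = np.ones(areas.size, dtype=bool)
    is_hole[0] = False
    is_hole[touching] = False
    if math.isfinite(params.max_hole_area):
        is_hole &= areas * pixel_area_km2 <= params.max_hole_area
    return is_hole[labels]


def _distance_to_subset(zeros: np.ndarray, pad_with_zero: bool) -> np.ndarray:
    """Pixel-unit EDT to the nearest True cell of ``zeros`` (inf if none),
    optionally surrounding the grid with virtual True cells."""
    if pad_with_zero:
        padded = np.pad(~zeros, 1, constant_values=False)
        return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    if not zeros.any():
        return np.full(zeros.shape, np.inf)
    return ndimage.distance_transform_edt(~zeros)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def classify_fragmentation(
    landscape: BinaryLandscape, params: FragParams | None = None
) -> FragmentationMap:
    """Classify every forest pixel into the six fragmentation classes.

    Algorithm:

    1. core candidates = forest pixels with distance-to-nonforest
       strictly greater than ``edge_width``;
    2. contiguous core tracts (forest connectivity) are assigned core1 /
       core2 / core3 by tract area against the acre thresholds
       (core2 is the closed interval);
    3. interior openings ("holes") are non-forest components (hole
       connectivity) not touching the grid boundary, up to
       ``max_hole_area``;
    4. each remaining forest pixel is **perforated** if its nearest
       non-forest pixel lies in a hole — strictly nearer than any
       exterior non-forest (ties resolve to edge) — otherwise **edge**;
    5. forest fragments (forest connectivity) containing no core pixel
       are relabelled **patch** wholesale.
    """
    params = params or FragParams()
    forest = landscape.forest_mask(params.nodata_as)
    ps = landscape.pixel_size
    pixel_area_km2 = ps**2 / 1e6
    classes = np.zeros(forest.shape, dtype=np.uint8)
    if not forest.any():
        return FragmentationMap(classes, params, ps, landscape.origin,
                                landscape.crs_id, landscape.epoch_year)

    # (1) core pixels
    d = distance_to_nonforest(landscape, params)
    core = forest & (d > params.edge_width)

    # (2) core tracts by size
    core_labels, core_areas_px = label_components(core, params.forest_connectivity)
    if core_labels.max() > 0:
        tract_km2 = core_areas_px * pixel_area_km2
        tract_class = np.zeros(tract_km2.size, dtype=np.uint8)
        tract_class[tract_km2 < params.core_small_max] = CLASS_CORE1
        tract_class[(tract_km2 >= params.core_small_max) &
                    (tract_km2 <= params.core_medium_max)] = CLASS_CORE2
        tract_class[tract_km2 > params.core_medium_max] = CLASS_CORE3
        tract_class[0] = 0
        classes[core] = tract_class[core_labels[core]]

    # (3) holes; (4) perforated vs edge via nearest-nonforest identity
    periphery = forest & ~core
    if periphery.any():
        nonforest = ~forest
        holes = _hole_mask(nonforest, params, pixel_area_km2)
        exterior_nf = nonforest & ~holes
        d_hole = _distance_to_subset(holes, pad_with_zero=False)
        d_ext = _distance_to_subset(
            exterior_nf, pad_with_zero=(params.boundary_policy == "outside_is_nonforest")
        )
        perforated = periphery & (d_hole < d_ext)
        classes[perforated] = CLASS_PERFORATED
        classes[periphery & ~perforated] = CLASS_EDGE

    # (5) coreless fragments become patch
    frag_labels, _ = label_components(forest, params.forest_connectivity)
    n_frag = frag_labels.max()
    if n_frag > 0:
        has_core = np.zeros(n_frag + 1, dtype=bool)
        if core.any():
            has_core[np.unique(frag_labels[core])] = True
        patchy = forest & ~has_core[frag_labels]
        classes[patchy] = CLASS_PATCH

    return FragmentationMap(classes, params, ps, landscape.origin,
                            landscape.crs_id, landscape.epoch_year)


def class_area_summary(fmap: FragmentationMap) -> ClassAreaTable:
    """Per-class area table; Σ forest-class areas equals forest area
    exactly (in pixel counts)."""
    counts = fmap.pixel_counts()
    pixel_area_km2 = fmap.pixel_size**2 / 1e6
    areas = {name: n * pixel_area_km2 for name, n in counts.items()}
    return ClassAreaTable(areas_km2=areas, pixel_counts=counts, epoch_year=fmap.epoch_year)


def write_class_raster(fmap: FragmentationMap, path) -> None:
    """Write a class raster as ASCII grid + sidecar (codes and params)."""
    from .landscape import BinaryLandscape, write_ascii_grid

    frame = BinaryLandscape(
        np.zeros(fmap.shape, dtype=np.int8),
        pixel_size=fmap.pixel_size,
        origin=fmap.origin,
        crs_id=fmap.crs_id,
        epoch_year=fmap.epoch_year,
    )
    write_ascii_grid(
        frame,
        path,
        values=fmap.classes,
        nodata_value=255,
        metadata={
            "class_codes": {v: k for k, v in CLASS_NAMES.items()},
            "frag_params": fmap.params.to_dict(),
        },
    )


def read_class_raster(path) -> FragmentationMap:
    from .landscape import read_ascii_grid

    grid, meta = read_ascii_grid(path)
    pdict = meta.get("frag_params", {})
    if pdict.get("max_hole_area") is None:
        pdict["max_hole_area"] = math.inf
    params = FragParams(**pdict) if pdict else FragParams()
    nrow = int(meta["nrows"])
    cellsize = float(meta["cellsize"])
    origin = (float(meta.get("xllcorner", 0.0)),
              float(meta.get("yllcorner", 0.0)) + nrow * cellsize)
    year = meta.get("epoch_year")
    return FragmentationMap(
        grid.astype(np.uint8), params, cellsize, origin,
        str(meta.get("crs_id", "unknown")), None if year is None else int(year),
    )
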