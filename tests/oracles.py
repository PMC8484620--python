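"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive nearest-pixel
scans, stack-based flood fill, per-pixel edge counting — and shares no
code path with the package implementation (no scipy.ndimage).
"""

from __future__ import annotations

import math

import numpy as np

NONFOREST, FOREST = 0, 1
PATCH, EDGE, PERFORATED, CORE1, CORE2, CORE3 = 1, 2, 3, 4, 5, 6


def flood_fill_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, list[int]]:
    """Stack-based connected-component labelling, labels 1..K in
    row-major order of each component's first pixel."""
    mask = np.asarray(mask, dtype=bool)
    nrow, ncol = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    areas = []
    next_label = 1
    for r0 in range(nrow):
        for c0 in range(ncol):
            if mask[r0, c0] and labels[r0, c0] == 0:
                stack = [(r0, c0)]
                labels[r0, c0] = next_label
                count = 0
                while stack:
                    r, c = stack.pop()
                    count += 1
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrow and 0 <= cc < ncol and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = next_label
                            stack.append((rr, cc))
                areas.append(count)
                next_label += 1
    return labels, areas


def _min_sq_dist_to(points_rc: np.ndarray, r: int, c: int) -> float:
    """Minimum squared centre-to-centre distance (pixel units) from
    (r, c) to any of the given pixels; inf if none."""
    if points_rc.size == 0:
        return math.inf
    d2 = (points_rc[:, 0] - r) ** 2 + (points_rc[:, 1] - c) ** 2
    return float(d2.min())


def _sq_dist_outside(r: int, c: int, nrow: int, ncol: int) -> float:
    """Squared distance (pixel units) to the nearest virtual non-forest
    cell outside the grid."""
    return float(min(r + 1, nrow - r, c + 1, ncol - c)) ** 2


def oracle_distance_to_nonforest(forest: np.ndarray, pixel_size: float,
                                 outside_is_nonforest: bool = True) -> np.ndarray:
    """Exhaustive nearest-nonforest-pixel scan; metres."""
    forest = np.asarray(forest, dtype=bool)
    nrow, ncol = forest.shape
    nf = np.argwhere(~forest)
    out = np.zeros(forest.shape)
    for r in range(nrow):
        for c in range(ncol):
            if not forest[r, c]:
                continue
            d2 = _min_sq_dist_to(nf, r, c)
            if outside_is_nonforest:
                d2 = min(d2, _sq_dist_outside(r, c, nrow, ncol))
            out[r, c] = math.sqrt(d2) * pixel_size
    return out


def oracle_classify(forest: np.ndarray, pixel_size: float, *,
                    edge_width: float = 100.0,
                    core_small_max: float = 250 * 4046.8564224 / 1e6,
                    core_medium_max: float = 500 * 4046.8564224 / 1e6,
                    outside_is_nonforest: bool = True,
                    forest_connectivity: int = 8,
                    hole_connectivity: int = 4,
                    max_hole_area: float = math.inf) -> np.ndarray:
    """Literal rule-by-rule fragmentation classification."""
    forest = np.asarray(forest, dtype=bool)
    nrow, ncol = forest.shape
    pixel_km2 = pixel_size**2 / 1e6
    classes = np.zeros(forest.shape, dtype=np.uint8)

    # rule 1: core = distance to nonforest strictly > edge_width
    dist = oracle_distance_to_nonforest(forest, pixel_size, outside_is_nonforest)
    if not outside_is_nonforest and not (~forest).any():
        dist = np.where(forest, math.inf, 0.0)
    core = forest & (dist > edge_width)

    # rule 2: core tracts by size
    core_labels, core_areas = flood_fill_label(core, forest_connectivity)
    for k, npix in enumerate(core_areas, start=1):
        a = npix * pixel_km2
        if a < core_small_max:
            cls = CORE1
        elif a <= core_medium_max:
            cls = CORE2
        else:
            cls = CORE3
        classes[core_labels == k] = cls

    # rule 3: holes
    nf_labels, nf_areas = flood_fill_label(~forest, hole_connectivity)
    hole = np.zeros(forest.shape, dtype=bool)
    for k, npix in enumerate(nf_areas, start=1):
        comp = nf_labels == k
        touches = comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any()
        if not touches and npix * pixel_km2 <= max_hole_area:
            hole |= comp
    hole_rc = np.argwhere(hole)
    ext_rc = np.argwhere(~forest & ~hole)

    # rule 4: perforated iff the nearest nonforest is strictly a hole
    for r in range(nrow):
        for c in range(ncol):
            if not forest[r, c] or core[r, c]:
                continue
            d2_hole = _min_sq_dist_to(hole_rc, r, c)
            d2_ext = _min_sq_dist_to(ext_rc, r, c)
            if outside_is_nonforest:
                d2_ext = min(d2_ext, _sq_dist_outside(r, c, nrow, ncol))
            classes[r, c] = PERFORATED if d2_hole < d2_ext else EDGE

    # rule 5: coreless forest components become patch wholesale
    f_labels, f_areas = flood_fill_label(forest, forest_connectivity)
    for k in range(1, len(f_areas) + 1):
        comp = f_labels == k
        if not (core & comp).any():
            classes[comp] = PATCH
    return classes


def oracle_patch_table(forest: np.ndarray, pixel_size: float,
                       connectivity: int = 8,
                       outside_is_nonforest: bool = True):
    """Per-patch pixel count and perimeter by exhaustive edge scan.

    Returns list of (pixels, perimeter_m) in label order.
    """
    forest = np.asarray(forest, dtype=bool)
    nrow, ncol = forest.shape
    labels, areas = flood_fill_label(forest, connectivity)
    perims = [0] * len(areas)
    for r in range(nrow):
        for c in range(ncol):
            if not forest[r, c]:
                continue
            lab = labels[r, c] - 1
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol:
                    if not forest[rr, cc]:
                        perims[lab] += 1
                elif outside_is_nonforest:
                    perims[lab] += 1
    return [(a, p * pixel_size) for a, p in zip(areas, perims)]
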