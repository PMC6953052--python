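"""Measurement stages: correction, segmentation, puncta detection,
per-cell assignment, lysosome-to-nucleus distances, and storage-material
(subunit c) deposit quantification.

Conventions
-----------
* Label maps are 2-D integer grids; 0 is background, labels are contiguous
  positive integers ordered by object centroid (row, then column) so that
  output is reproducible bit-for-bit.
* "Diameter" / "width" filters use the maximum caliper (Feret) extent of the
  connected region.
* Boundary pixels of an object are its pixels 4-adjacent to non-object
  pixels; the lysosome-to-nucleus distance is the Euclidean distance from a
  vesicle centroid to the nearest nuclear boundary pixel center, and 0 for a
  centroid lying inside the nucleus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class DetectionParams:
    """All tunable thresholds of the measurement stages."""

    # nuclei (defaults follow the published segmentation rules: structures
    # 30-70 px in diameter and >= 500 grayscales above local background)
    nucleus_diameter_px: tuple[float, float] = (30.0, 70.0)
    nucleus_min_above_background: float = 500.0
    nucleus_smooth_sigma: float = 1.0
    # border refinement level as a fraction of each nucleus's peak height
    # above its annulus-estimated local background.  Distances are measured
    # to boundary-pixel CENTERS, which sit on average half a pixel inside
    # the contour; with a ~1 px edge width the contour at Phi(-0.5) ~ 0.31
    # of peak height lies half a pixel outside the half-max edge and
    # compensates for that offset.
    nucleus_border_level: float = 0.31
    # vesicles / puncta
    spot_sigma_px: float = 1.5
    spot_diameter_px: tuple[float, float] = (1.0, 14.0)
    spot_margin: float = 2500.0
    # cells
    cell_max_radius_px: float = 60.0
    cell_smooth_sigma: float = 3.0
    assign_max_gap_px: float = 5.0
    # deposits (published rules: width > 15 px, >= 20,000 above background)
    deposit_min_width_px: float = 15.0
    deposit_min_above_background: float = 20000.0
    # shared
    background_sigma: float = 50.0
    positive_threshold: int = 5
    exclude_border_cells: bool = False


@dataclass
class CellRecord:
    """One segmented cell's measurements."""

    cell_id: int
    nucleus_id: int
    green_count: int
    red_distances: list[float] = dc_field(default_factory=list)
    is_positive: bool = False


def _relabel_sorted(labels: np.ndarray) -> np.ndarray:
    """Relabel objects 1..n ordered by centroid (row, column)."""
    props = regionprops(labels)
    order = sorted(props, key=lambda p: p.centroid)
    out = np.zeros_like(labels)
    for new, p in enumerate(order, start=1):
        out[labels == p.label] = new
    return out


# ---------------------------------------------------------------------------
# flat-field correction


def flat_field_correct(
    image: np.ndarray,
    model: np.ndarray | None = None,
    smoothing_sigma: float | None = None,
) -> np.ndarray:
    """Divide an image by its illumination surface, preserving mean intensity.

    With ``model=None`` the surface is estimated by heavy Gaussian smoothing
    of the image itself.  An all-zero image is returned unchanged with a
    warning.
    """
    img = np.asarray(image, dtype=float)
    if not np.any(img):
        warnings.warn("flat_field_correct: all-zero image returned unchanged")
        return img.copy()
    if model is None:
        sigma = smoothing_sigma or max(img.shape) / 8.0
        surface = ndi.gaussian_filter(img, sigma)
    else:
        surface = np.asarray(model, dtype=float)
        if surface.shape != img.shape:
            raise ValueError("illumination model shape does not match image")
    eps = 1e-6 * float(surface.max())
    corrected = img / np.maximum(surface, max(eps, 1e-12))
    corrected *= img.mean() / corrected.mean()
    return corrected


def _local_background(img: np.ndarray, sigma: float) -> np.ndarray:
    return ndi.gaussian_filter(img, sigma)


# ---------------------------------------------------------------------------
# nuclei


def segment_nuclei(
    nuclear_channel: np.ndarray,
    diameter_range_px: tuple[float, float] = (30.0, 70.0),
    min_above_background: float = 500.0,
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Segment nuclei as bright structures whose caliper diameter lies in
    ``diameter_range_px`` and whose peak exceeds local background by
    ``min_above_background``; touching nuclei are split by seeded watershed.

    Returns a label map (possibly empty; an empty image is not an error).
    """
    p = params or DetectionParams()
    img = np.asarray(nuclear_channel, dtype=float)
    smooth = ndi.gaussian_filter(img, p.nucleus_smooth_sigma)
    fg = smooth - _local_background(img, p.background_sigma)
    mask = fg > 0.5 * min_above_background
    mask = ndi.binary_fill_holes(mask)
    lo, hi = diameter_range_px
    # drop specks well below the admissible size before watershed
    mask = _remove_small(mask, min_area=max(4, int(np.pi * (lo / 2.0) ** 2 / 4)))
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    min_sep = max(3, int(lo * 0.5))
    coords = peak_local_max(
        distance, min_distance=min_sep, labels=sk_label(mask), exclude_border=False
    )
    coords = sorted(map(tuple, coords))
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(coords, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        return np.zeros(img.shape, dtype=np.int32)
    labels = watershed(-distance, markers, mask=mask)

    # all-candidate exclusion zone for the per-object background annuli
    near_any = ndi.binary_dilation(mask, iterations=3)

    keep = np.zeros(img.shape, dtype=np.int32)
    h, w = img.shape
    for prop in regionprops(labels):
        # work on a padded bounding box for speed
        pad = 10
        y0, x0, y1, x1 = prop.bbox
        sl = (slice(max(0, y0 - pad), min(h, y1 + pad)),
              slice(max(0, x0 - pad), min(w, x1 + pad)))
        region = labels[sl] == prop.label
        sm = smooth[sl]
        # local background from an annulus around the object, excluding the
        # neighbourhood of any candidate object
        ring = ndi.binary_dilation(region, iterations=8) & ~near_any[sl]
        if ring.any():
            bg_local = float(np.median(sm[ring]))
        else:
            bg_local = float(np.percentile(smooth, 25))
        peak = float(sm[region].max())
        if peak - bg_local < min_above_background:
            continue
        # refine the border; see DetectionParams.nucleus_border_level
        level = bg_local + p.nucleus_border_level * (peak - bg_local)
        refined = region & (sm > level)
        lab_ref, n_ref = ndi.label(refined)
        if n_ref == 0:
            continue
        if n_ref > 1:
            sizes = ndi.sum_labels(np.ones_like(lab_ref), lab_ref, np.arange(1, n_ref + 1))
            refined = lab_ref == (int(np.argmax(sizes)) + 1)
        rprop = regionprops(refined.astype(np.int32))[0]
        d = rprop.feret_diameter_max
        if not lo <= d <= hi:
            continue
        keep[sl][refined] = prop.label
    return _relabel_sorted(keep)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    bad = np.flatnonzero(sizes < min_area) + 1
    if bad.size:
        mask = mask & ~np.isin(lab, bad)
    return mask


# ---------------------------------------------------------------------------
# vesicles


def detect_vesicles(
    channel: np.ndarray,
    channel_kind: str = "green",
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Detect small bright puncta with a band-pass (difference-of-Gaussians)
    filter, a background-relative threshold, and a size filter.

    Touching puncta are split: each local maximum of the band-pass response
    above the margin seeds one vesicle, and the above-margin support is
    divided among the seeds by watershed.

    The band-pass response of a constant offset is exactly zero, so detection
    is invariant to adding a constant to the whole channel.
    """
    if channel_kind not in ("green", "red"):
        raise ValueError(f"unknown channel_kind {channel_kind!r}")
    p = params or DetectionParams()
    img = np.asarray(channel, dtype=float)
    narrow = ndi.gaussian_filter(img, p.spot_sigma_px)
    wide = ndi.gaussian_filter(img, 4.0 * p.spot_sigma_px)
    dog = narrow - wide
    mask = dog > p.spot_margin
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    coords = peak_local_max(
        dog,
        min_distance=max(1, int(round(p.spot_sigma_px))),
        threshold_abs=p.spot_margin,
        exclude_border=False,
    )
    coords = sorted(map(tuple, coords))
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (y, x) in enumerate(coords, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        return np.zeros(img.shape, dtype=np.int32)
    labels = watershed(-dog, markers, mask=mask)
    lo, hi = p.spot_diameter_px
    keep = np.zeros_like(labels, dtype=np.int32)
    for prop in regionprops(labels):
        d = 1.0 if prop.area == 1 else prop.feret_diameter_max
        if lo <= d <= hi:
            keep[labels == prop.label] = prop.label
    return _relabel_sorted(keep)


def vesicle_centroids(vesicle_labels: np.ndarray, intensity: np.ndarray | None = None) -> np.ndarray:
    """(n, 2) array of vesicle centroids in (row, col) pixel coordinates,
    ordered by label; intensity-weighted when an intensity image is given."""
    props = regionprops(vesicle_labels, intensity_image=intensity)
    props = sorted(props, key=lambda p: p.label)
    if intensity is not None:
        return np.array([p.weighted_centroid for p in props], float).reshape(-1, 2)
    return np.array([p.centroid for p in props], float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# cell regions


def infer_cell_regions(
    red_channel: np.ndarray,
    nuclei: np.ndarray,
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Seeded watershed from the nuclei over the smoothed Lysotracker
    background landscape, clipped to the cytoplasmic foreground and to a
    maximum radius around each nucleus.  Exactly one region per nucleus.
    """
    p = params or DetectionParams()
    if nuclei.max() == 0:
        return np.zeros_like(np.asarray(nuclei, dtype=np.int32))
    img = np.asarray(red_channel, dtype=float)
    landscape = ndi.gaussian_filter(img, p.cell_smooth_sigma)
    bg = float(np.percentile(landscape, 5))
    hi = float(np.percentile(landscape, 99))
    threshold = bg + 0.25 * (hi - bg)
    foreground = landscape > threshold
    foreground |= nuclei > 0
    within = ndi.distance_transform_edt(nuclei == 0) <= p.cell_max_radius_px
    mask = foreground & within
    return watershed(-landscape, markers=nuclei.astype(np.int32), mask=mask)


# ---------------------------------------------------------------------------
# assignment and measurement


def assign_vesicles_to_cells(
    vesicles: np.ndarray,
    cells: np.ndarray,
    max_gap_px: float = 5.0,
    centroids: np.ndarray | None = None,
) -> tuple[dict[int, list[int]], int]:
    """Assign each vesicle to the cell region containing its centroid.

    A centroid on background is assigned to the nearest region within
    ``max_gap_px``; farther vesicles are dropped and counted.  Returns
    ``(cell_id -> vesicle labels, n_dropped)``.
    """
    if vesicles.shape != cells.shape:
        raise ValueError("vesicle and cell label maps differ in shape")
    if centroids is None:
        centroids = vesicle_centroids(vesicles)
    assignments: dict[int, list[int]] = {}
    dropped = 0
    nearest = None
    for vid, (cy, cx) in enumerate(centroids, start=1):
        iy = int(np.clip(round(cy), 0, cells.shape[0] - 1))
        ix = int(np.clip(round(cx), 0, cells.shape[1] - 1))
        cell = int(cells[iy, ix])
        if cell == 0:
            if nearest is None:
                nearest = ndi.distance_transform_edt(cells == 0, return_indices=True)
            dist, (ind_y, ind_x) = nearest
            if dist[iy, ix] <= max_gap_px:
                cell = int(cells[ind_y[iy, ix], ind_x[iy, ix]])
        if cell == 0:
            dropped += 1
            continue
        assignments.setdefault(cell, []).append(vid)
    return assignments, dropped


def nucleus_boundary_pixels(nuclei: np.ndarray, nucleus_id: int | None = None) -> np.ndarray:
    """(n, 2) coordinates of nuclear pixels 4-adjacent to background.

    With ``nucleus_id=None`` the boundary pixels of all nuclei are returned.
    """
    mask = nuclei > 0 if nucleus_id is None else nuclei == nucleus_id
    interior = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def distance_to_nuclear_border(
    centroid: tuple[float, float],
    nuclei: np.ndarray,
    nucleus_id: int | None = None,
    um_per_pixel: float = 1.0,
    boundary: np.ndarray | None = None,
) -> float:
    """Shortest Euclidean distance (um) from a vesicle centroid to the
    nearest nuclear border; 0 if the centroid lies inside a nucleus.

    By default the minimum is taken over the borders of all nuclei (the
    nearest nuclear border); pass ``nucleus_id`` to restrict to one nucleus.
    """
    cy, cx = centroid
    iy = int(np.clip(round(cy), 0, nuclei.shape[0] - 1))
    ix = int(np.clip(round(cx), 0, nuclei.shape[1] - 1))
    inside = nuclei[iy, ix] > 0 if nucleus_id is None else nuclei[iy, ix] == nucleus_id
    if inside:
        return 0.0
    if boundary is None:
        boundary = nucleus_boundary_pixels(nuclei, nucleus_id)
    if boundary.size == 0:
        return float("nan")
    d2 = (boundary[:, 0] - cy) ** 2 + (boundary[:, 1] - cx) ** 2
    return float(np.sqrt(d2.min())) * um_per_pixel


def measure_cells(
    cells: np.ndarray,
    nuclei: np.ndarray,
    green_vesicles: np.ndarray,
    red_vesicles: np.ndarray,
    um_per_pixel: float = 1.0,
    positive_threshold: int = 5,
    max_gap_px: float = 5.0,
) -> list[CellRecord]:
    """Per cell: GFP-LC3 puncta count and per-red-vesicle distances to the
    nearest border of that cell's nucleus.

    Each red-vesicle distance is taken to the nearest nuclear border over
    all nuclei (for a vesicle within its own cell this is its own nucleus).
    Cells whose region contains no nucleus are excluded and logged.
    """
    # map cell -> its nucleus (each region should contain exactly one)
    cell_ids = np.unique(cells)
    cell_ids = cell_ids[cell_ids > 0]
    nucleus_of: dict[int, int] = {}
    for cid in cell_ids:
        labs = np.unique(nuclei[cells == cid])
        labs = labs[labs > 0]
        if labs.size == 0:
            log.info("cell %d has no nucleus; excluded from records", cid)
            continue
        nucleus_of[int(cid)] = int(labs[0])

    green_assign, _ = assign_vesicles_to_cells(green_vesicles, cells, max_gap_px)
    red_centroids = vesicle_centroids(red_vesicles)
    red_assign, _ = assign_vesicles_to_cells(
        red_vesicles, cells, max_gap_px, centroids=red_centroids
    )

    all_boundary = nucleus_boundary_pixels(nuclei)
    records = []
    for cid in sorted(nucleus_of):
        nid = nucleus_of[cid]
        green_count = len(green_assign.get(cid, []))
        distances = [
            distance_to_nuclear_border(
                tuple(red_centroids[vid - 1]),
                nuclei,
                um_per_pixel=um_per_pixel,
                boundary=all_boundary,
            )
            for vid in red_assign.get(cid, [])
        ]
        records.append(
            CellRecord(
                cell_id=cid,
                nucleus_id=nid,
                green_count=green_count,
                red_distances=distances,
                is_positive=green_count >= positive_threshold,
            )
        )
    return records


# ---------------------------------------------------------------------------
# subunit-c deposits


def detect_subunit_c_deposits(
    green_channel: np.ndarray,
    nuclei: np.ndarray,
    min_width_px: float = 15.0,
    min_above_background: float = 20000.0,
    background_sigma: float = 50.0,
) -> tuple[np.ndarray, float | None]:
    """Detect storage-material deposits: structures strictly wider than
    ``min_width_px`` (maximum caliper) and at least ``min_above_background``
    grayscales above local background.

    Returns the deposit label map and deposits-per-cell (deposit count over
    nuclei count; ``None`` when the field has no nuclei).
    """
    img = np.asarray(green_channel, dtype=float)
    fg = img - _local_background(img, background_sigma)
    mask = fg > 0.5 * min_above_background
    labels = sk_label(mask, connectivity=1)
    keep = np.zeros_like(labels, dtype=np.int32)
    for prop in regionprops(labels):
        if prop.area == 1:
            continue
        if prop.feret_diameter_max <= min_width_px:
            continue
        region = labels == prop.label
        if fg[region].max() < min_above_background:
            continue
        keep[region] = prop.label
    keep = _relabel_sorted(keep)
    n_deposits = int(keep.max())
    n_nuclei = int(np.unique(nuclei[nuclei > 0]).size)
    per_cell = None if n_nuclei == 0 else n_deposits / n_nuclei
    return keep, per_cell
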