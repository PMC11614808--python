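"""Automated nuclear colocalization counting and manual-rule marker scoring.

Pipeline per channel plane: preprocess (unsharp mask, Gaussian blur, optional
edge step) -> threshold ensemble (Otsu / multi-Otsu / local) -> mask
combination -> small-object removal -> pixelwise AND between the two channel
masks -> second small-object removal -> connected components counted inside
the region of interest, normalized to ROI area (per mm²) or curvilinear
distance (per mm).

Connectivity is 8-connected throughout. Otsu-family thresholds operate on a
256-bin histogram spanning the plane's observed min-max (bins configurable
for the multi-class variant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .errors import (
    DegenerateInputError,
    DimensionError,
    ParameterError,
)
from .imaging import (
    ImageStack,
    RegionOfInterest,
    distance_to_polyline,
    point_in_polygon,
    polygon_area,
    polyline_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "LabeledObjects",
    "CountRecord",
    "preprocess",
    "threshold_otsu",
    "threshold_multi_otsu",
    "threshold_local",
    "binarize_otsu",
    "binarize_multi_otsu",
    "combine_masks",
    "filter_small",
    "colocalize",
    "segment_channel",
    "count_coloc",
    "count_single_marker",
    "score_cells",
]

DEFAULT_MIN_AREA_PX = 15  # objects under 15 px² are treated as artifacts


@dataclass
class SegmentationParams:
    """Tunable knobs of the counting pipeline.

    Defaults follow the documented conventions: majority vote over the three
    threshold methods, 15 px² minimum object area applied both per channel and
    after the AND overlay, per-plane z handling, edge step off.
    """

    unsharp_radius_px: float = 0.0
    unsharp_amount: float = 0.0
    gaussian_sigma_px: float = 0.0
    edge_mode: str = "off"  # off | subtract | watershed_split
    threshold_methods: tuple[str, ...] = ("otsu", "multi_otsu", "local")
    multi_otsu_classes: int = 3
    local_block_px: int = 51
    local_offset: float = 0.0
    combine_rule: str = "majority"  # majority | intersection | union
    min_area_px: int = DEFAULT_MIN_AREA_PX
    area_filter_stage: str = "both"  # pre_and | post_and | both
    z_mode: str = "per_plane"  # per_plane | max_projection
    roi_band_halfwidth_px: float = 200.0
    n_bins: int = 256
    min_contrast_ratio: float = 4.0

    def __post_init__(self) -> None:
        if not self.threshold_methods:
            raise ParameterError("threshold_methods must be non-empty")
        bad = set(self.threshold_methods) - {"otsu", "multi_otsu", "local"}
        if bad:
            raise ParameterError(f"unknown threshold methods: {sorted(bad)}")
        if self.local_block_px % 2 == 0:
            raise ParameterError("local_block_px must be odd")
        if self.min_area_px < 0:
            raise ParameterError("min_area_px must be >= 0")
        if self.unsharp_radius_px < 0 or self.gaussian_sigma_px < 0:
            raise ParameterError("radii and sigmas must be >= 0")
        if self.multi_otsu_classes < 2:
            raise ParameterError("multi_otsu_classes must be >= 2")
        if self.edge_mode not in ("off", "subtract", "watershed_split"):
            raise ParameterError(f"unknown edge_mode {self.edge_mode!r}")
        if self.combine_rule not in ("majority", "intersection", "union"):
            raise ParameterError(f"unknown combine_rule {self.combine_rule!r}")
        if self.z_mode not in ("per_plane", "max_projection"):
            raise ParameterError(f"unknown z_mode {self.z_mode!r}")
        if self.area_filter_stage not in ("pre_and", "post_and", "both"):
            raise ParameterError(f"unknown area_filter_stage {self.area_filter_stage!r}")
        if self.min_contrast_ratio < 1.0:
            raise ParameterError("min_contrast_ratio must be >= 1")


@dataclass
class ObjectRecord:
    object_id: int
    area_px: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]


@dataclass
class LabeledObjects:
    """Connected components surviving the area filter on one plane."""

    channel: str
    z_index: int
    label_image: np.ndarray
    objects: list[ObjectRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objects)


@dataclass
class CountRecord:
    """A normalized object count for one sample / marker combination."""

    sample_id: str
    marker_combo: str
    raw_count: int
    density: float
    normalizer: float  # mm (polyline) or mm² (polygon)
    normalizer_kind: str  # "length_mm" | "area_mm2"
    line: str = ""
    treatment: str = ""
    dpi: int | None = None
    per_plane_counts: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "line": self.line,
            "treatment": self.treatment,
            "dpi": self.dpi,
            "marker_combo": self.marker_combo,
            "raw_count": self.raw_count,
            "normalizer": self.normalizer,
            "normalizer_kind": self.normalizer_kind,
            "density": self.density,
        }


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _sobel_magnitude(plane: np.ndarray) -> np.ndarray:
    gr = ndimage.sobel(plane, axis=0, mode="reflect")
    gc = ndimage.sobel(plane, axis=1, mode="reflect")
    return np.hypot(gr, gc)


def preprocess(plane: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Unsharp mask, then Gaussian blur, then the optional edge step.

    Output is clipped to the input's [min, max] range. With
    ``unsharp_amount=0``, ``gaussian_sigma_px=0`` and ``edge_mode='off'``
    this is the identity.
    """
    plane = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(plane)):
        raise ParameterError("plane contains non-finite values")
    if np.any(plane < 0):
        raise ParameterError("plane contains negative intensities")
    if params.unsharp_radius_px < 0 or params.gaussian_sigma_px < 0:
        raise ParameterError("negative radius/sigma")

    lo, hi = float(plane.min()), float(plane.max())
    out = plane
    if params.unsharp_amount != 0:
        blurred = ndimage.gaussian_filter(out, params.unsharp_radius_px)
        out = out + params.unsharp_amount * (out - blurred)
    if params.gaussian_sigma_px > 0:
        out = ndimage.gaussian_filter(out, params.gaussian_sigma_px)
    if params.edge_mode == "subtract":
        out = out - _sobel_magnitude(out)
    # watershed_split acts at the labeling stage, not on intensities
    return np.clip(out, lo, hi)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def _quantize(plane: np.ndarray, n_bins: int) -> tuple[np.ndarray, float, float]:
    """Map intensities to integer bin indices 0..n_bins-1 over observed min-max."""
    plane = np.asarray(plane, dtype=float)
    lo, hi = float(plane.min()), float(plane.max())
    if hi <= lo:
        raise DegenerateInputError("constant plane: no threshold exists")
    q = np.floor((plane - lo) / (hi - lo) * n_bins).astype(np.int64)
    np.clip(q, 0, n_bins - 1, out=q)
    return q, lo, hi


def _otsu_bin(hist: np.ndarray) -> int:
    """Index k maximizing between-class variance, background = bins <= k."""
    n = hist.sum()
    levels = np.arange(len(hist), dtype=float)
    w0 = np.cumsum(hist)
    w1 = n - w0
    mu = np.cumsum(hist * levels)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu / w0
        m1 = (mu_t - mu) / w1
        sigma_b = w0 * w1 * (m0 - m1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    if not np.any(np.isfinite(sigma_b)):
        raise DegenerateInputError("cannot split histogram into two classes")
    return int(np.argmax(sigma_b))


def threshold_otsu(plane: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold over an ``n_bins``-bin histogram of the plane.

    Returns the intensity at the lower edge of the first foreground bin;
    pixels at or above the returned value are foreground
    (see :func:`binarize_otsu`).
    """
    q, lo, hi = _quantize(plane, n_bins)
    hist = np.bincount(q.ravel(), minlength=n_bins)
    k = _otsu_bin(hist)
    return lo + (k + 1) * (hi - lo) / n_bins


def binarize_otsu(plane: np.ndarray, n_bins: int = 256) -> np.ndarray:
    q, _, _ = _quantize(plane, n_bins)
    hist = np.bincount(q.ravel(), minlength=n_bins)
    return q > _otsu_bin(hist)


def _multi_otsu_bins(hist: np.ndarray, classes: int) -> tuple[int, ...]:
    """Exhaustive search over bin cut points minimizing within-class variance.

    Equivalent to maximizing Σ w_c·μ_c² over all choices of ``classes-1``
    ordered cut indices; cuts are the last bin of each lower class.
    """
    n_bins = len(hist)
    occupied = np.flatnonzero(hist)
    if len(occupied) < classes:
        raise DegenerateInputError(
            f"only {len(occupied)} occupied bins for {classes} classes"
        )
    levels = np.arange(n_bins, dtype=float)
    cw = np.concatenate([[0.0], np.cumsum(hist)])
    cm = np.concatenate([[0.0], np.cumsum(hist * levels)])

    def class_score(a: int, b: int) -> float:
        # bins a..b inclusive; returns w * mu^2, -inf if empty
        w = cw[b + 1] - cw[a]
        if w == 0:
            return -math.inf
        m = (cm[b + 1] - cm[a]) / w
        return w * m * m

    best: tuple[float, tuple[int, ...]] = (-math.inf, ())
    # candidate cuts need only be at occupied bins
    for cuts in combinations(occupied[:-1], classes - 1):
        score = 0.0
        prev = 0
        ok = True
        for c in cuts:
            s = class_score(prev, int(c))
            if s == -math.inf:
                ok = False
                break
            score += s
            prev = int(c) + 1
        if ok:
            s = class_score(prev, n_bins - 1)
            if s == -math.inf:
                continue
            score += s
            if score > best[0]:
                best = (score, tuple(int(c) for c in cuts))
    if not best[1]:
        raise DegenerateInputError("no valid multi-Otsu partition")
    return best[1]


def threshold_multi_otsu(
    plane: np.ndarray, classes: int = 3, n_bins: int = 256
) -> np.ndarray:
    """Multi-Otsu thresholds (``classes - 1`` ascending intensity values).

    Each returned value is the lower edge of the first bin of the next class;
    foreground for segmentation purposes is the top class.
    """
    if classes < 2:
        raise ParameterError("classes must be >= 2")
    q, lo, hi = _quantize(plane, n_bins)
    hist = np.bincount(q.ravel(), minlength=n_bins)
    cuts = _multi_otsu_bins(hist, classes)
    width = (hi - lo) / n_bins
    return np.array([lo + (k + 1) * width for k in cuts])


def binarize_multi_otsu(
    plane: np.ndarray, classes: int = 3, n_bins: int = 256
) -> np.ndarray:
    """Binary mask of the top multi-Otsu class."""
    if classes < 2:
        raise ParameterError("classes must be >= 2")
    q, _, _ = _quantize(plane, n_bins)
    hist = np.bincount(q.ravel(), minlength=n_bins)
    cuts = _multi_otsu_bins(hist, classes)
    return q > cuts[-1]


def threshold_local(
    plane: np.ndarray, block_px: int, offset: float = 0.0
) -> np.ndarray:
    """Adaptive mean threshold: foreground iff value > block mean + offset.

    A positive offset makes the test stricter (constant planes yield an empty
    mask), a negative one more permissive. The block mean uses mirror
    boundary handling (edge pixel repeated, scipy's ``reflect``).
    """
    plane = np.asarray(plane, dtype=float)
    if block_px % 2 == 0:
        raise ParameterError("block_px must be odd")
    if block_px >= min(plane.shape):
        raise ParameterError(
            f"block_px={block_px} must be < min(plane dims)={min(plane.shape)}"
        )
    local_mean = ndimage.uniform_filter(plane, size=block_px, mode="reflect")
    return plane > (local_mean + offset)


def combine_masks(masks: list[np.ndarray], rule: str = "majority") -> np.ndarray:
    """Combine binary masks by majority vote, intersection, or union."""
    if not masks:
        raise ParameterError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise DimensionError(f"mask shapes differ: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=bool) for m in masks])
    if rule == "majority":
        return stack.sum(axis=0) * 2 > len(masks)
    if rule == "intersection":
        return stack.all(axis=0)
    if rule == "union":
        return stack.any(axis=0)
    raise ParameterError(f"unknown combine rule {rule!r}")


# ---------------------------------------------------------------------------
# components / colocalization
# ---------------------------------------------------------------------------


def _label_objects(
    mask: np.ndarray, channel: str = "", z_index: int = 0
) -> LabeledObjects:
    labels = measure.label(mask, connectivity=2)
    objs = [
        ObjectRecord(
            object_id=int(p.label),
            area_px=int(p.area),
            centroid=(float(p.centroid[0]), float(p.centroid[1])),
            bbox=tuple(int(v) for v in p.bbox),
        )
        for p in measure.regionprops(labels)
    ]
    return LabeledObjects(channel=channel, z_index=z_index, label_image=labels, objects=objs)


def filter_small(
    mask: np.ndarray,
    min_area_px: int,
    channel: str = "",
    z_index: int = 0,
) -> tuple[np.ndarray, LabeledObjects]:
    """Remove 8-connected components with area < ``min_area_px``."""
    mask = np.asarray(mask, dtype=bool)
    labeled = _label_objects(mask, channel, z_index)
    keep_ids = {o.object_id for o in labeled.objects if o.area_px >= min_area_px}
    if len(keep_ids) == len(labeled.objects):
        filtered_mask = mask.copy()
        filtered = labeled
    else:
        keep = np.isin(labeled.label_image, sorted(keep_ids))
        filtered_mask = mask & keep
        filtered = _label_objects(filtered_mask, channel, z_index)
    return filtered_mask, filtered


def colocalize(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixelwise binary AND of two masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise DimensionError(f"shape mismatch {mask_a.shape} vs {mask_b.shape}")
    return mask_a & mask_b


def _watershed_split(mask: np.ndarray) -> np.ndarray:
    """Split touching objects by watershed on the distance transform."""
    if not mask.any():
        return measure.label(mask, connectivity=2)
    dist = ndimage.distance_transform_edt(mask)
    peaks = morphology.local_maxima(ndimage.gaussian_filter(dist, 1.0))
    markers = measure.label(peaks & mask, connectivity=2)
    if markers.max() == 0:
        return measure.label(mask, connectivity=2)
    return segmentation.watershed(-dist, markers, mask=mask)


def segment_channel(
    plane: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, dict]:
    """Preprocess + threshold-ensemble one plane into a binary mask.

    Degenerate planes (constant after preprocessing) yield an empty mask and
    a warning in the returned log dict, never an exception.
    """
    pre = preprocess(plane, params)
    masks = []
    log: dict = {"thresholds": {}, "degenerate": False, "skipped": []}
    for method in params.threshold_methods:
        try:
            if method == "otsu":
                t = threshold_otsu(pre, params.n_bins)
                masks.append(binarize_otsu(pre, params.n_bins))
                log["thresholds"]["otsu"] = t
            elif method == "multi_otsu":
                ts = threshold_multi_otsu(pre, params.multi_otsu_classes, params.n_bins)
                masks.append(
                    binarize_multi_otsu(pre, params.multi_otsu_classes, params.n_bins)
                )
                log["thresholds"]["multi_otsu"] = [float(t) for t in ts]
            elif method == "local":
                masks.append(
                    threshold_local(pre, params.local_block_px, params.local_offset)
                )
                log["thresholds"]["local"] = f"block={params.local_block_px}"
        except DegenerateInputError as exc:
            # a method that cannot split this plane is dropped from the vote
            logger.debug("method %s degenerate on plane: %s", method, exc)
            log["skipped"].append(method)
    if not masks:
        logger.warning(
            "all threshold methods degenerate; treating channel as empty"
        )
        return np.zeros(plane.shape, dtype=bool), {**log, "degenerate": True}
    combined = combine_masks(masks, params.combine_rule)
    # a plane with no real signal still gets split by the ensemble (the
    # threshold lands inside the noise); reject masks whose foreground is not
    # clearly brighter than the background
    if combined.any() and (~combined).any():
        fg = float(pre[combined].mean())
        bg = float(pre[~combined].mean())
        ratio = fg / bg if bg > 0 else np.inf
        log["contrast_ratio"] = ratio
        if ratio < params.min_contrast_ratio:
            logger.warning(
                "foreground/background contrast %.2f below %.2f; "
                "treating channel as empty",
                ratio,
                params.min_contrast_ratio,
            )
            return np.zeros(plane.shape, dtype=bool), {**log, "degenerate": True}
    return combined, log


def _roi_member(
    centroid: tuple[float, float], roi: RegionOfInterest, band_halfwidth_px: float
) -> bool:
    if roi.kind == "polygon":
        return point_in_polygon(centroid, roi.vertices)
    return distance_to_polyline(centroid, roi.vertices) <= band_halfwidth_px


def _normalizer(roi: RegionOfInterest, pixel_size_um: float) -> tuple[float, str]:
    if roi.kind == "polygon":
        return polygon_area(roi, pixel_size_um) / 1e6, "area_mm2"
    return polyline_length(roi, pixel_size_um) / 1e3, "length_mm"


def _planes(channel_zyx: np.ndarray, z_mode: str) -> list[np.ndarray]:
    if z_mode == "max_projection":
        return [channel_zyx.max(axis=0)]
    return [channel_zyx[z] for z in range(channel_zyx.shape[0])]


def _count_in_roi(
    mask: np.ndarray,
    roi: RegionOfInterest,
    params: SegmentationParams,
) -> int:
    if params.edge_mode == "watershed_split":
        labels = _watershed_split(mask)
        props = measure.regionprops(labels)
        centroids = [p.centroid for p in props if p.area >= params.min_area_px]
    else:
        _, labeled = filter_small(mask, 0)
        centroids = [o.centroid for o in labeled.objects]
    return sum(
        1 for c in centroids if _roi_member(c, roi, params.roi_band_halfwidth_px)
    )


def count_coloc(
    stack: ImageStack,
    ch_a: str,
    ch_b: str,
    roi: RegionOfInterest,
    params: SegmentationParams | None = None,
    sample_id: str = "",
    **labels,
) -> CountRecord:
    """Count objects colocalized between two channels, normalized to the ROI.

    Runs the full pipeline per plane (or on the max projection): segment each
    channel, area-filter per channel (if configured), AND the masks,
    area-filter the AND mask (if configured), then count components whose
    centroid lies in the polygon ROI or within the polyline band.
    """
    params = params or SegmentationParams()
    for ch in (ch_a, ch_b):
        if not stack.has_channel(ch):
            raise KeyError(f"channel {ch!r} missing from stack")

    pre_filter = params.area_filter_stage in ("pre_and", "both")
    post_filter = params.area_filter_stage in ("post_and", "both")

    planes_a = _planes(stack.channel(ch_a), params.z_mode)
    planes_b = _planes(stack.channel(ch_b), params.z_mode)
    per_plane: list[int] = []
    for z, (pa, pb) in enumerate(zip(planes_a, planes_b)):
        mask_a, log_a = segment_channel(pa, params)
        mask_b, log_b = segment_channel(pb, params)
        logger.debug("z=%d %s thresholds: %s", z, ch_a, log_a["thresholds"])
        logger.debug("z=%d %s thresholds: %s", z, ch_b, log_b["thresholds"])
        if pre_filter:
            mask_a, _ = filter_small(mask_a, params.min_area_px, ch_a, z)
            mask_b, _ = filter_small(mask_b, params.min_area_px, ch_b, z)
        both = colocalize(mask_a, mask_b)
        if post_filter:
            both, _ = filter_small(both, params.min_area_px, f"{ch_a}&{ch_b}", z)
        per_plane.append(_count_in_roi(both, roi, params))

    raw = int(sum(per_plane))
    norm, kind = _normalizer(roi, stack.pixel_size_um)
    return CountRecord(
        sample_id=sample_id,
        marker_combo=f"{ch_a}∧{ch_b}",
        raw_count=raw,
        density=raw / norm,
        normalizer=norm,
        normalizer_kind=kind,
        per_plane_counts=per_plane,
        **labels,
    )


def count_single_marker(
    stack: ImageStack,
    channel: str,
    roi: RegionOfInterest,
    params: SegmentationParams | None = None,
    sample_id: str = "",
    **labels,
) -> CountRecord:
    """Single-channel object count (the colocalization pipeline minus AND)."""
    params = params or SegmentationParams()
    if not stack.has_channel(channel):
        raise KeyError(f"channel {channel!r} missing from stack")
    planes = _planes(stack.channel(channel), params.z_mode)
    per_plane: list[int] = []
    for z, plane in enumerate(planes):
        mask, log = segment_channel(plane, params)
        logger.debug("z=%d %s thresholds: %s", z, channel, log["thresholds"])
        mask, _ = filter_small(mask, params.min_area_px, channel, z)
        per_plane.append(_count_in_roi(mask, roi, params))
    raw = int(sum(per_plane))
    norm, kind = _normalizer(roi, stack.pixel_size_um)
    return CountRecord(
        sample_id=sample_id,
        marker_combo=channel,
        raw_count=raw,
        density=raw / norm,
        normalizer=norm,
        normalizer_kind=kind,
        per_plane_counts=per_plane,
        **labels,
    )


# ---------------------------------------------------------------------------
# manual-rule scoring
# ---------------------------------------------------------------------------


def score_cells(
    cell_objects: LabeledObjects,
    nuclear_mask: np.ndarray,
    partner_mask: np.ndarray,
    rule: str = "nuclear_overlap",
    fraction_threshold: float | None = None,
    annulus_px: int = 3,
) -> dict[int, bool]:
    """Score each segmented cell against a partner channel.

    rule='nuclear_overlap': a cell is positive iff at least
    ``fraction_threshold`` (default 0.5) of the nucleus pixels it contains
    lie in the partner mask (e.g. leukocytes scored for nuclear PCNA).

    rule='surround': a cell's nucleus is positive iff at least
    ``fraction_threshold`` (default 0.3) of the annulus obtained by dilating
    the nucleus by ``annulus_px`` lies in the partner mask (e.g. HuC/D signal
    surrounding a DAPI nucleus).

    Cells containing no nucleus pixels are scored negative and logged.
    """
    if rule not in ("nuclear_overlap", "surround"):
        raise ParameterError(f"unknown scoring rule {rule!r}")
    if fraction_threshold is None:
        fraction_threshold = 0.5 if rule == "nuclear_overlap" else 0.3
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    partner_mask = np.asarray(partner_mask, dtype=bool)
    if nuclear_mask.shape != partner_mask.shape:
        raise DimensionError("nuclear and partner masks differ in shape")

    labels = cell_objects.label_image
    result: dict[int, bool] = {}
    selem = morphology.disk(annulus_px)
    for obj in cell_objects.objects:
        cell_px = labels == obj.object_id
        nucleus = cell_px & nuclear_mask
        if not nucleus.any():
            logger.info("cell %d has no contained nucleus; scored negative", obj.object_id)
            result[obj.object_id] = False
            continue
        if rule == "nuclear_overlap":
            frac = (nucleus & partner_mask).sum() / nucleus.sum()
        else:
            annulus = ndimage.binary_dilation(nucleus, structure=selem) & ~nucleus
            frac = (
                (annulus & partner_mask).sum() / annulus.sum() if annulus.any() else 0.0
            )
        result[obj.object_id] = bool(frac >= fraction_threshold)
    return result


def scored_count_record(
    scores: dict[int, bool],
    roi: RegionOfInterest,
    pixel_size_um: float,
    marker_combo: str,
    sample_id: str = "",
    **labels,
) -> CountRecord:
    """Wrap positive-cell scores into a normalized CountRecord."""
    raw = int(sum(scores.values()))
    norm, kind = _normalizer(roi, pixel_size_um)
    return CountRecord(
        sample_id=sample_id,
        marker_combo=marker_combo,
        raw_count=raw,
        density=raw / norm,
        normalizer=norm,
        normalizer_kind=kind,
        **labels,
    )
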