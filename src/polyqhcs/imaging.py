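"""Nuclei segmentation, whole-well counting and per-cell intensity.

A classical, fully parameterized stack stands in for the original
high-content pipeline: Gaussian smoothing, global Otsu threshold, hole
filling, distance-transform watershed declumping, area gating and
optional border exclusion.  Every step is deterministic given the image
and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed, expand_labels

__all__ = [
    "Image",
    "SegmentationParams",
    "NucleiMask",
    "segment_nuclei",
    "count_nuclei_in_well",
    "per_cell_intensity",
]


@dataclass
class Image:
    """Single-channel nonnegative intensity grid."""

    pixels: np.ndarray
    channel_label: str = "nuclear-stain"
    pixel_depth: int = 16

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if min(self.pixels.shape) < 16:
            raise ValueError("image must be at least 16x16")
        px = self.pixels.astype(float)
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("intensities must be finite and >= 0")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the nuclei-segmentation stack.

    smoothing_sigma      Gaussian pre-smoothing scale (px)
    threshold_method     'otsu' or a fixed numeric threshold
    min_area, max_area   retained object area gate (px)
    min_split_distance   minimum distance between watershed seeds (px)
    exclude_border       drop objects touching the image border
    """

    smoothing_sigma: float = 2.0
    threshold_method: object = "otsu"
    min_area: int = 40
    max_area: int = 2000
    min_split_distance: int = 8
    exclude_border: bool = False
    #: require the threshold to clear the image median by this many robust
    #: SDs; guards against Otsu bisecting pure background noise.  0 disables.
    min_contrast_sigmas: float = 3.0

    def validate(self) -> None:
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.smoothing_sigma < 0 or self.min_split_distance < 1:
            raise ValueError("smoothing_sigma >= 0 and min_split_distance >= 1 required")
        if self.min_contrast_sigmas < 0:
            raise ValueError("min_contrast_sigmas must be >= 0")


@dataclass
class NucleiMask:
    """Labelled nuclei: 0 = background, k = object k (labels consecutive)."""

    label_map: np.ndarray
    objects: pd.DataFrame = field(default_factory=pd.DataFrame)  # label, area, centroid, border
    qc_warning: Optional[str] = None

    @property
    def count(self) -> int:
        return len(self.objects)


def _as_image(img) -> Image:
    return img if isinstance(img, Image) else Image(pixels=np.asarray(img))


def segment_nuclei(img, params: SegmentationParams = SegmentationParams()) -> NucleiMask:
    """Detect nuclei in a nuclear-stain image.

    smooth -> global threshold -> fill holes -> distance-transform
    watershed declumping -> area gate -> optional border exclusion.
    Saturated or constant images yield zero objects with a QC warning
    rather than an exception.
    """
    img = _as_image(img)
    params.validate()
    px = img.pixels.astype(float)

    if px.max() == px.min():
        return NucleiMask(
            label_map=np.zeros(px.shape, dtype=np.int32),
            objects=_empty_objects(),
            qc_warning="constant image: no contrast to segment",
        )

    smoothed = gaussian(px, sigma=params.smoothing_sigma, preserve_range=True)
    if params.threshold_method == "otsu":
        thr = threshold_otsu(smoothed)
        if params.min_contrast_sigmas > 0:
            med = float(np.median(smoothed))
            robust_sd = 1.4826 * float(np.median(np.abs(smoothed - med)))
            if thr <= med + params.min_contrast_sigmas * robust_sd:
                return NucleiMask(np.zeros(px.shape, dtype=np.int32), _empty_objects(),
                                  qc_warning="threshold within background noise: "
                                             "no foreground contrast")
    else:
        thr = float(params.threshold_method)
    binary = smoothed > thr
    binary = ndimage.binary_fill_holes(binary)

    qc = None
    if not binary.any():
        return NucleiMask(np.zeros(px.shape, dtype=np.int32), _empty_objects(),
                          qc_warning="no foreground above threshold")
    if binary.mean() > 0.9:
        qc = "foreground covers >90% of the image (saturation suspected)"

    # declump touching nuclei: watershed on the distance transform, seeded
    # by local maxima at least min_split_distance apart
    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=params.min_split_distance,
        labels=binary, exclude_border=False)
    markers = np.zeros(px.shape, dtype=np.int32)
    # deterministic seed labels: peak_local_max returns peaks ordered by
    # descending distance value; relabel in raster order for stability
    order = np.lexsort((peaks[:, 1], peaks[:, 0])) if len(peaks) else []
    for i, j in enumerate(order, start=1):
        markers[tuple(peaks[j])] = i
    if markers.max() == 0:
        labels = ndimage.label(binary)[0]
    else:
        labels = watershed(-distance, markers=markers, mask=binary)

    # area gate and border exclusion, then consecutive relabeling
    rows = []
    keep = np.zeros(px.shape, dtype=np.int32)
    next_label = 0
    h, w = px.shape
    for prop in regionprops(labels):
        touches = (prop.bbox[0] == 0 or prop.bbox[1] == 0 or
                   prop.bbox[2] == h or prop.bbox[3] == w)
        if not (params.min_area <= prop.area <= params.max_area):
            continue
        if params.exclude_border and touches:
            continue
        next_label += 1
        keep[labels == prop.label] = next_label
        rows.append({"label": next_label, "area": int(prop.area),
                     "centroid_row": float(prop.centroid[0]),
                     "centroid_col": float(prop.centroid[1]),
                     "touches_border": bool(touches)})
    objects = pd.DataFrame(rows) if rows else _empty_objects()
    return NucleiMask(label_map=keep, objects=objects, qc_warning=qc)


def _empty_objects() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "area", "centroid_row",
                                 "centroid_col", "touches_border"])


def count_nuclei_in_well(images: Sequence, params: SegmentationParams = SegmentationParams()) -> int:
    """Total nuclei over the image tiles covering one well (sum of counts)."""
    images = list(images)
    if not images:
        raise ValueError("need at least one image per well")
    return sum(segment_nuclei(im, params).count for im in images)


def per_cell_intensity(
    signal_img,
    mask: NucleiMask,
    statistic: str = "mean",
    dilation_radius: int = 0,
) -> pd.DataFrame:
    """Per-object signal statistic over the (optionally dilated) regions.

    With ``dilation_radius`` > 0 each nuclear mask is expanded by that
    many pixels (never into a neighbour) as a cytoplasm proxy before
    averaging, for cytoplasmic dyes measured against a nuclear mask.
    """
    signal_img = _as_image(signal_img)
    if signal_img.pixels.shape != mask.label_map.shape:
        raise ValueError("signal image and mask dimensions differ")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    labels = mask.label_map
    if dilation_radius > 0:
        labels = expand_labels(labels, distance=dilation_radius)
    idx = mask.objects["label"].to_numpy() if len(mask.objects) else np.array([], dtype=int)
    px = signal_img.pixels.astype(float)
    # plain masked reduction per object: bit-identical to the per-pixel
    # definition of the statistic
    reducer = np.mean if statistic == "mean" else np.median
    vals = [float(reducer(px[labels == k])) for k in idx]
    return pd.DataFrame({"label": idx, "value": np.asarray(vals, dtype=float)})
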