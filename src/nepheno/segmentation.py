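"""Nucleus identification from the DAPI (or lamin) channel.

The approach mirrors a classic identify-primary-objects workflow: Gaussian
smoothing, global thresholding (Otsu by default), hole filling, connected
components, an area gate, and optional exclusion of border-touching
objects. Touching nuclei are not declumped by default; an optional
distance-transform watershed is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .io_formats import ChannelImage, LabeledMask

__all__ = ["SegmentationParams", "segment_nuclei", "gate_positive_nuclei"]


@dataclass
class SegmentationParams:
    """Thresholding and object-filter settings for nucleus segmentation.

    ``min_area``/``max_area`` are in pixels²; an object touching row 0,
    the last row, column 0 or the last column counts as border-touching.
    """

    smoothing_sigma: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area: float = 200.0
    max_area: float = 50000.0
    exclude_border: bool = True
    declump_watershed: bool = False

    def validate(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_method='fixed'")


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n in raster-scan order of each component's first pixel."""
    flat = labels.ravel()
    present, first = np.unique(flat, return_index=True)
    order = [lab for _, lab in sorted((f, l) for l, f in zip(present, first) if l > 0)]
    out = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def segment_nuclei(img: ChannelImage, params: SegmentationParams | None = None,
                   image_id: str = "") -> LabeledMask:
    """Identify nuclei as labeled connected components of the foreground.

    An all-constant image yields 0 objects. Labels are assigned in
    raster-scan order of each component's first pixel, so segmentation of
    the same image is reproducible and comparable across runs.
    """
    params = params or SegmentationParams()
    params.validate()
    pix = img.pixels.astype(np.float64)
    if params.smoothing_sigma > 0:
        pix = ndi.gaussian_filter(pix, params.smoothing_sigma)

    if pix.max() == pix.min():
        return LabeledMask(labels=np.zeros(pix.shape, dtype=np.int32), image_id=image_id)
    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    else:
        thr = threshold_otsu(pix)
    fg = pix > thr
    fg = ndi.binary_fill_holes(fg)

    if params.declump_watershed:
        dist = ndi.distance_transform_edt(fg)
        smooth_dist = ndi.gaussian_filter(dist, 2.0)
        peaks = cc_label(smooth_dist == ndi.maximum_filter(smooth_dist, size=7), connectivity=2)
        peaks[~fg] = 0
        labels = watershed(-dist, peaks, mask=fg)
    else:
        labels = cc_label(fg, connectivity=2)

    areas = np.bincount(labels.ravel())
    keep = np.zeros(areas.size, dtype=bool)
    keep[1:] = (areas[1:] >= params.min_area) & (areas[1:] <= params.max_area)
    if params.exclude_border:
        border = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
        keep[border[border > 0]] = False
    labels = np.where(keep[labels], labels, 0)
    labels = _relabel_raster_order(labels.astype(np.int32))
    return LabeledMask(labels=labels, image_id=image_id)


def gate_positive_nuclei(mask: LabeledMask, marker: ChannelImage,
                         min_mean_intensity: float) -> LabeledMask:
    """Retain only objects whose mean marker intensity meets the threshold.

    Used to restrict analysis to transfected (e.g. GFP-positive) nuclei.
    Surviving objects keep their original label numbers.
    """
    mask.require_same_shape(marker)
    labels = mask.labels
    present = mask.present_labels
    if present.size == 0:
        return LabeledMask(labels=labels.copy(), image_id=mask.image_id)
    means = ndi.mean(marker.pixels, labels=labels, index=present)
    keep = set(present[np.asarray(means) >= min_mean_intensity].tolist())
    out = np.where(np.isin(labels, list(keep)), labels, 0).astype(labels.dtype)
    return LabeledMask(labels=out, image_id=mask.image_id)
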