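"""Nuclear shape metrics and bleb calling by two-channel mask subtraction.

The headline readouts are the nuclear form factor 4πA/P² (1 for a perfect
circle, lower for deformed nuclei) and the percentage of blebbed nuclei.
A bleb is a chromatin protrusion through a gap in the lamina, so it is
DAPI-positive but lamin-B1-negative: candidates are the set difference
between a DAPI nucleus object and the hole-filled lamin object matched to
it, split into connected components and filtered by a minimum pixel area
to drop edge slivers and speckles.

Perimeter uses the Crofton multi-direction estimator. A naive 4-connected
pixel-edge count overestimates perimeter of a rasterized disk by ~13%,
biasing the form factor low by >20% and breaking the circle→1 anchor;
Crofton stays within a few percent for radii ≥ 20 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .io_formats import ChannelImage, LabeledMask

__all__ = [
    "BlebParams",
    "form_factor",
    "measure_nuclei",
    "match_objects",
    "detect_blebs",
    "bleb_counts_per_nucleus",
    "percent_blebbing",
    "summarize_morphometry",
]

_4PI = 4.0 * np.pi


def form_factor(area: float, perimeter: float) -> float:
    """Nuclear form factor 4πA/P².

    Equals 1 for a circle (A = πr², P = 2πr) and is smaller for any other
    shape (isoperimetric inequality); rasterized estimates can slightly
    exceed 1 because of perimeter-estimator bias.
    """
    if not (area > 0 and perimeter > 0):
        raise ValueError("area and perimeter must be positive")
    return _4PI * area / perimeter**2


@dataclass
class BlebParams:
    """Filters applied to bleb candidate components.

    ``min_bleb_area`` drops small false positives; ``edge_margin`` drops
    candidates that lie entirely within that many pixels of the filled
    lamin object boundary (thin rim slivers from imperfect channel
    registration rather than true protrusions).
    """

    min_bleb_area: float = 50.0
    edge_margin: int = 1

    def validate(self) -> None:
        if self.min_bleb_area < 0 or self.edge_margin < 0:
            raise ValueError("min_bleb_area and edge_margin must be >= 0")


def measure_nuclei(mask: LabeledMask, channels: dict[str, ChannelImage] | None = None,
                   image_id: str | None = None) -> pd.DataFrame:
    """Per-nucleus area, Crofton perimeter, form factor and channel means.

    Returns one row per label with columns ``image_id, label, area_px,
    perimeter_px, form_factor, border_touching`` plus a
    ``mean_intensity_<channel>`` column per requested channel.
    """
    channels = channels or {}
    for name, ch in channels.items():
        mask.require_same_shape(ch)
    labels = mask.labels
    if mask.n_objects == 0:
        cols = ["image_id", "label", "area_px", "perimeter_px", "form_factor", "border_touching"]
        cols += [f"mean_intensity_{n}" for n in channels]
        return pd.DataFrame(columns=cols)

    rows = []
    h, w = labels.shape
    for prop in regionprops(labels):
        area = float(prop.area)
        perim = float(prop.perimeter_crofton)
        r0, c0, r1, c1 = prop.bbox
        rows.append({
            "image_id": image_id if image_id is not None else mask.image_id,
            "label": int(prop.label),
            "area_px": area,
            "perimeter_px": perim,
            "form_factor": form_factor(area, perim) if perim > 0 else np.nan,
            "border_touching": bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
        })
    df = pd.DataFrame(rows)
    index = df["label"].to_numpy()
    for name, ch in channels.items():
        df[f"mean_intensity_{name}"] = np.asarray(
            ndi.mean(ch.pixels, labels=labels, index=index))
    return df


def match_objects(mask_a: LabeledMask, mask_b: LabeledMask) -> dict[int, int]:
    """One-to-one matching of labels across channels by maximal pixel overlap.

    Greedy assignment on descending overlap; ties broken by the smaller
    (a, b) label pair. Labels with no overlap stay unmatched.
    """
    mask_a.require_same_shape(mask_b)
    a, b = mask_a.labels.ravel(), mask_b.labels.ravel()
    both = (a > 0) & (b > 0)
    if not both.any():
        return {}
    pairs, counts = np.unique(np.stack([a[both], b[both]]), axis=1, return_counts=True)
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], pairs[0, i], pairs[1, i]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matching: dict[int, int] = {}
    for i in order:
        la, lb = int(pairs[0, i]), int(pairs[1, i])
        if la in used_a or lb in used_b:
            continue
        matching[la] = lb
        used_a.add(la)
        used_b.add(lb)
    return matching


def _fill_labels(labels: np.ndarray) -> np.ndarray:
    """Hole-fill each labeled object independently (rings become disks)."""
    out = labels.copy()
    for prop in regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        sub = labels[r0:r1, c0:c1] == prop.label
        filled = ndi.binary_fill_holes(sub)
        region = out[r0:r1, c0:c1]
        region[filled & (region == 0)] = prop.label
    return out


def detect_blebs(dapi_mask: LabeledMask, lamin_mask: LabeledMask,
                 params: BlebParams | None = None) -> tuple[pd.DataFrame, list[int]]:
    """Call blebs as DAPI-object pixels outside the matched, filled lamin object.

    For each DAPI nucleus matched to a lamin object, the candidate region
    is ``DAPI \\ filled(lamin)``; 8-connected components below
    ``min_bleb_area`` or lying entirely within ``edge_margin`` px of the
    filled lamin object are discarded. Returns a bleb table
    (``nucleus_label, bleb_id, area_px, centroid_r, centroid_c``) and the
    list of DAPI labels with no lamin match (excluded from bleb statistics).
    """
    params = params or BlebParams()
    params.validate()
    dapi_mask.require_same_shape(lamin_mask)
    lamin_filled = _fill_labels(lamin_mask.labels)
    matching = match_objects(dapi_mask, LabeledMask(lamin_filled))
    unmatched = [int(l) for l in dapi_mask.present_labels if int(l) not in matching]

    # all work happens inside per-pair bounding boxes: full-frame boolean
    # ops per nucleus are quadratic in image size and dominate runtime
    slices_d = ndi.find_objects(dapi_mask.labels)
    slices_l = ndi.find_objects(lamin_filled)
    h, w = dapi_mask.shape
    pad = params.edge_margin + 1
    rows = []
    bleb_id = 0
    struct = np.ones((3, 3), dtype=bool)
    for dapi_lab, lamin_lab in sorted(matching.items()):
        sd, sl = slices_d[dapi_lab - 1], slices_l[lamin_lab - 1]
        if sd is None or sl is None:
            continue
        r0 = max(0, min(sd[0].start, sl[0].start) - pad)
        r1 = min(h, max(sd[0].stop, sl[0].stop) + pad)
        c0 = max(0, min(sd[1].start, sl[1].start) - pad)
        c1 = min(w, max(sd[1].stop, sl[1].stop) + pad)
        box = (slice(r0, r1), slice(c0, c1))
        obj = dapi_mask.labels[box] == dapi_lab
        lam = lamin_filled[box] == lamin_lab
        candidate = obj & ~lam
        if not candidate.any():
            continue
        if params.edge_margin > 0:
            rim = ndi.binary_dilation(lam, structure=struct, iterations=params.edge_margin)
        else:
            rim = lam
        comp = cc_label(candidate, connectivity=2)
        for prop in regionprops(comp):
            if prop.area < params.min_bleb_area:
                continue
            comp_mask = comp == prop.label
            if np.all(rim[comp_mask]):
                continue  # boundary sliver, not a protrusion
            bleb_id += 1
            cy, cx = prop.centroid
            rows.append({
                "nucleus_label": int(dapi_lab),
                "bleb_id": bleb_id,
                "area_px": float(prop.area),
                "centroid_r": float(cy + r0),
                "centroid_c": float(cx + c0),
            })
    cols = ["nucleus_label", "bleb_id", "area_px", "centroid_r", "centroid_c"]
    return pd.DataFrame(rows, columns=cols), unmatched


def bleb_counts_per_nucleus(dapi_mask: LabeledMask, blebs: pd.DataFrame,
                            unmatched: list[int] | None = None) -> pd.DataFrame:
    """Per-nucleus ``n_blebs`` and ``bleb_area_total``; NaN for unmatched nuclei."""
    unmatched = set(unmatched or [])
    rows = []
    for lab in dapi_mask.present_labels:
        lab = int(lab)
        if lab in unmatched:
            rows.append({"label": lab, "n_blebs": np.nan, "bleb_area_total": np.nan})
        else:
            sel = blebs[blebs["nucleus_label"] == lab]
            rows.append({"label": lab, "n_blebs": float(len(sel)),
                         "bleb_area_total": float(sel["area_px"].sum())})
    return pd.DataFrame(rows, columns=["label", "n_blebs", "bleb_area_total"])


def percent_blebbing(n_blebs) -> float:
    """Percentage of nuclei with at least one bleb (NaN counts excluded)."""
    arr = np.asarray(n_blebs, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no nuclei with a defined bleb count")
    return 100.0 * float(np.mean(arr >= 1))


def summarize_morphometry(records: pd.DataFrame, condition_col: str = "condition",
                          replicate_col: str = "replicate") -> pd.DataFrame:
    """Mean ± SD form factor and % blebbing per replicate and pooled.

    Rows with ``replicate == 'pooled'`` aggregate all nuclei of a
    condition; the per-replicate rows are the unit on which condition-level
    tests should run.
    """
    if records.empty:
        raise ValueError("empty record set")

    def _summary(sub: pd.DataFrame) -> dict:
        out = {
            "n_nuclei": len(sub),
            "form_factor_mean": float(sub["form_factor"].mean()),
            "form_factor_sd": float(sub["form_factor"].std(ddof=1)) if len(sub) > 1 else np.nan,
        }
        if "n_blebs" in sub.columns and sub["n_blebs"].notna().any():
            out["percent_blebbing"] = percent_blebbing(sub["n_blebs"])
        return out

    rows = []
    for cond, cond_df in records.groupby(condition_col, sort=True):
        if replicate_col in records.columns:
            for rep, rep_df in cond_df.groupby(replicate_col, sort=True):
                rows.append({condition_col: cond, replicate_col: rep, **_summary(rep_df)})
        rows.append({condition_col: cond, replicate_col: "pooled", **_summary(cond_df)})
    return pd.DataFrame(rows)
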