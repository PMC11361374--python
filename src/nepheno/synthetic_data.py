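"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators:

* two-channel nucleus images (DAPI + lamin-B1 ring) with planted chromatin
  blebs protruding past the lamina and planted diffraction-limited foci;
* FRAP traces following ``y = y0 + (a - y0)(1 - exp(-b x))`` with
  exponential background photobleaching of the reference region;
* negative-binomial count matrices with sample size factors and planted
  differentially expressed genes at a specified log2 fold change.

All generators are deterministic given their seed: the same spec + seed
produces bit-identical output. Geometry is exact before blur/noise: with
``blur_sigma = 0`` and ``noise_sd = 0`` thresholding the DAPI channel at
``background_level`` recovers the true nucleus ∪ bleb masks pixel for pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .io_formats import ChannelImage

__all__ = [
    "NucleusImageSpec",
    "GroundTruth",
    "FrapSimSpec",
    "FrapTrace",
    "CountSimSpec",
    "CountSim",
    "PlacementError",
    "make_nucleus_image",
    "make_foci_image",
    "simulate_frap",
    "simulate_counts",
    "sample_count",
]


class PlacementError(RuntimeError):
    """Nuclei could not be placed without overlap within the retry budget."""


# count distributions for per-nucleus bleb/foci numbers: either a fixed
# integer, ("bernoulli", p) or ("poisson", lam)
CountDist = "int | tuple[str, float]"


def sample_count(dist, rng: np.random.Generator) -> int:
    """Draw one count from a fixed int, ('bernoulli', p) or ('poisson', lam)."""
    if isinstance(dist, (int, np.integer)):
        if dist < 0:
            raise ValueError("count must be >= 0")
        return int(dist)
    kind, param = dist
    if kind == "bernoulli":
        if not 0.0 <= param <= 1.0:
            raise ValueError("bernoulli p must be in [0, 1]")
        return int(rng.random() < param)
    if kind == "poisson":
        if param < 0:
            raise ValueError("poisson rate must be >= 0")
        return int(rng.poisson(param))
    raise ValueError(f"unknown count distribution {dist!r}")


@dataclass
class NucleusImageSpec:
    """Parameters of a synthetic two-channel nucleus field.

    Nuclei are ellipses (semi-major axis drawn from ``radius_range``,
    eccentricity from ``eccentricity_range``, random orientation) placed
    without overlap by rejection sampling. The DAPI channel is the union of
    the ellipse interiors and any planted bleb disks attached to the ellipse
    boundary; the lamin channel is the elliptical boundary ring only, so a
    bleb is DAPI-positive and lamin-negative by construction. Foci are
    rendered in a separate marker channel (see :func:`make_foci_image`) as
    Gaussian spots of width ``focus_sigma``.

    Intensities are in arbitrary units: ``background_level`` everywhere plus
    ``nucleus_intensity`` (``ring_intensity``) inside objects, followed by
    Gaussian blur of ``blur_sigma`` and additive N(0, ``noise_sd``) noise
    clipped at zero.
    """

    image_size: tuple[int, int] = (512, 512)
    n_nuclei: int = 8
    radius_range: tuple[float, float] = (18.0, 28.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    ring_width: float = 3.0
    blebs_per_nucleus: object = 0
    bleb_radius_range: tuple[float, float] = (6.0, 10.0)
    foci_per_nucleus: object = 0
    focus_sigma: float = 1.5
    focus_amplitude: float = 200.0
    min_focus_separation: float | None = None  # default 6 * focus_sigma
    nucleus_intensity: float = 1000.0
    ring_intensity: float = 1000.0
    blur_sigma: float = 1.0
    noise_sd: float = 10.0
    background_level: float = 100.0
    seed: int = 0
    max_place_retries: int = 1000

    def validate(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size too small")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if rmin <= self.ring_width:
            raise ValueError("radius_range min must exceed ring_width")
        emin, emax = self.eccentricity_range
        if not (0.0 <= emin <= emax < 1.0):
            raise ValueError("eccentricity_range must lie in [0, 1)")
        bmin, bmax = self.bleb_radius_range
        if not (0 < bmin <= bmax):
            raise ValueError("bleb_radius_range must satisfy 0 < min <= max")
        for v, name in [(self.blur_sigma, "blur_sigma"), (self.noise_sd, "noise_sd"),
                        (self.focus_sigma, "focus_sigma"), (self.background_level, "background_level")]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring detections against.

    ``nucleus_labels`` and ``bleb_labels`` are full-frame integer rasters
    (0 = background). Bleb masks are the protruding part of each bleb disk,
    i.e. disk minus ellipse, and are disjoint from the lamin ring. Focus
    coordinates are (row, col) centroids, each strictly inside its nucleus.
    """

    nucleus_labels: np.ndarray
    bleb_labels: np.ndarray
    bleb_to_nucleus: dict = field(default_factory=dict)
    bleb_areas: dict = field(default_factory=dict)
    foci: dict = field(default_factory=dict)  # nucleus label -> list[(r, c)]
    border_touching: dict = field(default_factory=dict)
    nuclei_params: list = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.border_touching)

    def n_blebs(self, nucleus_label: int) -> int:
        return sum(1 for n in self.bleb_to_nucleus.values() if n == nucleus_label)

    def foci_count(self, nucleus_label: int) -> int:
        return len(self.foci.get(nucleus_label, []))

    def to_json(self, path: str | Path) -> Path:
        """Serialize the geometric description (not the rasters) as JSON."""
        payload = {
            "nuclei": self.nuclei_params,
            "bleb_to_nucleus": {str(k): int(v) for k, v in self.bleb_to_nucleus.items()},
            "bleb_areas": {str(k): int(v) for k, v in self.bleb_areas.items()},
            "foci": {str(k): [[float(r), float(c)] for r, c in v] for k, v in self.foci.items()},
            "border_touching": {str(k): bool(v) for k, v in self.border_touching.items()},
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1))
        return path


def _ellipse_mask(shape, center, axes, theta):
    """Boolean raster of an axis-rotated filled ellipse (local evaluation)."""
    cy, cx = center
    a, b = axes
    rad = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - rad), min(shape[0], int(cy) + rad + 1)
    x0, x1 = max(0, int(cx) - rad), min(shape[1], int(cx) + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = local
    return out


def _disk_mask(shape, center, radius):
    cy, cx = center
    rad = int(np.ceil(radius)) + 2
    y0, y1 = max(0, int(cy) - rad), min(shape[0], int(cy) + rad + 1)
    x0, x1 = max(0, int(cx) - rad), min(shape[1], int(cx) + rad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    local = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = local
    return out


def _finish_channel(signal: np.ndarray, spec: NucleusImageSpec, rng: np.random.Generator,
                    channel: str) -> ChannelImage:
    img = signal.astype(np.float64)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)
    return ChannelImage(pixels=img, channel=channel)


def _plant_nuclei(spec: NucleusImageSpec, rng: np.random.Generator, with_blebs: bool):
    """Place non-overlapping ellipses; return truth rasters and ring mask."""
    shape = tuple(spec.image_size)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    bleb_labels = np.zeros(shape, dtype=np.int32)
    ring_mask = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    truth = GroundTruth(nucleus_labels=nucleus_labels, bleb_labels=bleb_labels)

    bleb_id = 0
    bmax = spec.bleb_radius_range[1] if with_blebs else 0.0
    for label in range(1, spec.n_nuclei + 1):
        placed = False
        for _ in range(spec.max_place_retries):
            a = rng.uniform(*spec.radius_range)
            ecc = rng.uniform(*spec.eccentricity_range)
            b = a * np.sqrt(1.0 - ecc**2)
            theta = rng.uniform(0, np.pi)
            margin = a + 2 * bmax + 3
            if 2 * margin >= min(shape):
                raise ValueError("nuclei too large for image_size")
            cy = rng.uniform(margin, shape[0] - 1 - margin)
            cx = rng.uniform(margin, shape[1] - 1 - margin)

            ellipse = _ellipse_mask(shape, (cy, cx), (a, b), theta)
            n_blebs = sample_count(spec.blebs_per_nucleus, rng) if with_blebs else 0
            blebs = []
            for _ in range(n_blebs):
                for _ in range(50):
                    t = rng.uniform(0, 2 * np.pi)
                    rb = rng.uniform(*spec.bleb_radius_range)
                    # attachment point on the ellipse boundary
                    by = cy + a * np.cos(t) * np.sin(theta) + b * np.sin(t) * np.cos(theta)
                    bx = cx + a * np.cos(t) * np.cos(theta) - b * np.sin(t) * np.sin(theta)
                    disk = _disk_mask(shape, (by, bx), rb)
                    protrusion = disk & ~ellipse
                    if protrusion.sum() >= 3:
                        blebs.append((disk, protrusion, (by, bx), rb))
                        break
            dapi_obj = ellipse.copy()
            for disk, _, _, _ in blebs:
                dapi_obj |= disk
            # keep a few pixels of clearance between neighbouring objects
            ys, xs = np.nonzero(dapi_obj)
            if ys.size == 0:
                continue
            y0, y1 = ys.min(), ys.max() + 1
            x0, x1 = xs.min(), xs.max() + 1
            pad = 3
            y0p, x0p = max(0, y0 - pad), max(0, x0 - pad)
            y1p, x1p = min(shape[0], y1 + pad), min(shape[1], x1 + pad)
            grown_local = binary_dilation(dapi_obj[y0p:y1p, x0p:x1p], iterations=pad)
            if (occupied[y0p:y1p, x0p:x1p] & grown_local).any():
                continue
            occupied[y0p:y1p, x0p:x1p] |= grown_local

            nucleus_labels[ellipse] = label
            inner = _ellipse_mask(shape, (cy, cx), (max(a - spec.ring_width, 0.5),
                                                    max(b - spec.ring_width, 0.5)), theta)
            ring_mask |= ellipse & ~inner
            for disk, protrusion, bc, rb in blebs:
                bleb_id += 1
                bleb_labels[protrusion] = bleb_id
                truth.bleb_to_nucleus[bleb_id] = label
                truth.bleb_areas[bleb_id] = int(protrusion.sum())
            touches = (ellipse[0, :].any() or ellipse[-1, :].any()
                       or ellipse[:, 0].any() or ellipse[:, -1].any())
            truth.border_touching[label] = bool(touches)
            truth.nuclei_params.append({
                "label": label, "center": [float(cy), float(cx)],
                "axes": [float(a), float(b)], "theta": float(theta),
                "blebs": [{"center": [float(bc[0]), float(bc[1])], "radius": float(rb)}
                          for _, _, bc, rb in blebs],
            })
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {label} after {spec.max_place_retries} retries"
            )
    return truth, ring_mask


def make_nucleus_image(spec: NucleusImageSpec):
    """Render a two-channel (DAPI, lamin B1) field of synthetic nuclei.

    Returns
    -------
    (dapi, lamin, truth)
        ``dapi`` covers nucleus ellipses plus planted bleb disks; ``lamin``
        is the boundary ring of each ellipse only, so planted blebs are
        lamin-negative (the lamina gap a real bleb protrudes through).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth, ring_mask = _plant_nuclei(spec, rng, with_blebs=True)

    dapi_sig = np.full(spec.image_size, spec.background_level, dtype=np.float64)
    obj = (truth.nucleus_labels > 0) | (truth.bleb_labels > 0)
    dapi_sig[obj] += spec.nucleus_intensity
    lamin_sig = np.full(spec.image_size, spec.background_level, dtype=np.float64)
    lamin_sig[ring_mask] += spec.ring_intensity

    dapi = _finish_channel(dapi_sig, spec, rng, "dapi")
    lamin = _finish_channel(lamin_sig, spec, rng, "laminB1")
    return dapi, lamin, truth


def make_foci_image(spec: NucleusImageSpec):
    """Render a marker channel with planted Gaussian foci plus a DAPI channel.

    Foci centroids are drawn strictly inside each nucleus (at least
    ``2 + 2*focus_sigma`` px from the boundary) and pairwise separated by
    ``min_focus_separation`` (default ``6 * focus_sigma``) so that each
    planted focus is individually resolvable; spots have peak amplitude
    ``focus_amplitude`` over the diffuse background, so the planted
    peak SNR is ``focus_amplitude / noise_sd``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth, _ = _plant_nuclei(spec, rng, with_blebs=False)
    shape = tuple(spec.image_size)
    min_sep = (spec.min_focus_separation if spec.min_focus_separation is not None
               else 6.0 * spec.focus_sigma)

    marker_sig = np.full(shape, spec.background_level, dtype=np.float64)
    for params in truth.nuclei_params:
        label = params["label"]
        n_foci = sample_count(spec.foci_per_nucleus, rng)
        cy, cx = params["center"]
        a, b = params["axes"]
        theta = params["theta"]
        inset = 2.0 + 2.0 * spec.focus_sigma
        coords = []
        for _ in range(n_foci):
            for _ in range(200):
                t = rng.uniform(0, 2 * np.pi)
                rho = np.sqrt(rng.uniform(0, 1))
                u = rho * max(a - inset, 1.0) * np.cos(t)
                v = rho * max(b - inset, 1.0) * np.sin(t)
                fy = cy + u * np.sin(theta) + v * np.cos(theta)
                fx = cx + u * np.cos(theta) - v * np.sin(theta)
                iy, ix = int(round(fy)), int(round(fx))
                if truth.nucleus_labels[iy, ix] == label and all(
                    (fy - oy) ** 2 + (fx - ox) ** 2 > min_sep**2
                    for oy, ox in coords
                ):
                    coords.append((fy, fx))
                    break
        truth.foci[label] = coords
        rad = int(np.ceil(5 * spec.focus_sigma))
        for fy, fx in coords:
            y0, y1 = max(0, int(fy) - rad), min(shape[0], int(fy) + rad + 1)
            x0, x1 = max(0, int(fx) - rad), min(shape[1], int(fx) + rad + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            marker_sig[y0:y1, x0:x1] += spec.focus_amplitude * np.exp(
                -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * spec.focus_sigma**2)
            )

    dapi_sig = np.full(shape, spec.background_level, dtype=np.float64)
    dapi_sig[truth.nucleus_labels > 0] += spec.nucleus_intensity
    marker = _finish_channel(marker_sig, spec, rng, "marker")
    dapi = _finish_channel(dapi_sig, spec, rng, "dapi")
    return marker, dapi, truth


# ---------------------------------------------------------------------------
# FRAP traces


@dataclass
class FrapSimSpec:
    """Kinetic and acquisition parameters of a simulated FRAP trace.

    The recovery follows ``y = y0 + (a - y0)(1 - exp(-b x))`` in post-bleach
    time ``x``; the pre-bleach plateau is normalized to 1.0 and the bleach
    is instantaneous between the last pre-bleach and first post-bleach
    frame. Both the ROI and the unbleached reference region decay as
    ``exp(-reference_decay_rate * t)`` (acquisition photobleaching), which
    the reference-ratio correction cancels exactly. Noise is additive
    Gaussian on the ROI channel.
    """

    y0: float = 0.2
    a: float = 0.7
    b: float = 0.1
    n_prebleach: int = 3
    n_postbleach: int = 90
    interval: float = 1.0
    reference_decay_rate: float = 0.002
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if not 0.0 <= self.y0 <= self.a:
            raise ValueError("require 0 <= y0 <= a")
        if self.n_prebleach < 1 or self.n_postbleach < 1:
            raise ValueError("need at least 1 pre- and post-bleach frame")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.noise_sd < 0 or self.reference_decay_rate < 0:
            raise ValueError("noise_sd and reference_decay_rate must be >= 0")


@dataclass
class FrapTrace:
    """Raw FRAP time series: ROI and reference intensities per frame."""

    t: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (len(self.t) == len(self.roi) == len(self.reference)):
            raise ValueError("t, roi, reference must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.n_prebleach < 1 or self.n_prebleach >= len(self.t):
            raise ValueError("n_prebleach out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.t)),
            "time_s": self.t,
            "roi_intensity": self.roi,
            "ref_intensity": self.reference,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_prebleach: int = 3) -> "FrapTrace":
        return cls(t=df["time_s"].to_numpy(), roi=df["roi_intensity"].to_numpy(),
                   reference=df["ref_intensity"].to_numpy(), n_prebleach=n_prebleach)


def frap_model(x: np.ndarray, y0: float, a: float, b: float) -> np.ndarray:
    """Single-exponential recovery ``y0 + (a - y0)(1 - exp(-b x))``."""
    return y0 + (a - y0) * (1.0 - np.exp(-b * np.asarray(x, dtype=float)))


def simulate_frap(spec: FrapSimSpec) -> FrapTrace:
    """Emit one FRAP trace: plateau, instantaneous bleach, recovery."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_prebleach + spec.n_postbleach
    t = np.arange(n, dtype=float) * spec.interval
    x = t[spec.n_prebleach:] - t[spec.n_prebleach]
    model = np.ones(n)
    model[spec.n_prebleach:] = frap_model(x, spec.y0, spec.a, spec.b)
    decay = np.exp(-spec.reference_decay_rate * t)
    roi = model * decay
    if spec.noise_sd > 0:
        roi = roi + rng.normal(0.0, spec.noise_sd, size=n)
    return FrapTrace(t=t, roi=roi, reference=decay, n_prebleach=spec.n_prebleach)


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountSimSpec:
    """Negative-binomial count-matrix simulation with planted DE genes.

    Per-gene means are log-normal (``exp(N(mean_log, sd_log))``); counts are
    NB with variance ``mu + dispersion * mu**2`` (dispersion shared across
    genes; Poisson when dispersion is ~0). A fraction ``de_fraction`` of
    genes has its group-2 mean multiplied by ``2**planted_log2fc``; each
    sample's mean is additionally scaled by its size factor.
    """

    n_genes: int = 5000
    n_samples_per_group: int = 3
    size_factors: tuple | None = None
    mean_log: float = 5.0
    sd_log: float = 1.5
    dispersion: float = 0.1
    de_fraction: float = 0.0
    planted_log2fc: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("need >= 1 gene and >= 1 sample per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.size_factors is not None:
            if len(self.size_factors) != 2 * self.n_samples_per_group:
                raise ValueError("size_factors must have one entry per sample")
            if any(s <= 0 for s in self.size_factors):
                raise ValueError("size_factors must be positive")


@dataclass
class CountSim:
    counts: pd.DataFrame          # genes x samples, non-negative integers
    groups: pd.Series             # sample -> group label ("g1"/"g2")
    truth: pd.DataFrame           # gene, is_de, log2fc


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(spec: CountSimSpec) -> CountSim:
    """Draw a genes × samples NB count matrix with recorded planted DE."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g, m = spec.n_genes, spec.n_samples_per_group
    genes = [f"gene_{i:05d}" for i in range(g)]
    samples = [f"g1_s{j}" for j in range(m)] + [f"g2_s{j}" for j in range(m)]
    groups = pd.Series(["g1"] * m + ["g2"] * m, index=samples, name="group")
    sf = np.ones(2 * m) if spec.size_factors is None else np.asarray(spec.size_factors, float)

    mu = np.exp(rng.normal(spec.mean_log, spec.sd_log, size=g))
    n_de = int(round(spec.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    lfc = np.zeros(g)
    lfc[de_idx] = spec.planted_log2fc

    mean_matrix = np.empty((g, 2 * m))
    mean_matrix[:, :m] = mu[:, None] * sf[None, :m]
    mean_matrix[:, m:] = (mu * 2.0**lfc)[:, None] * sf[None, m:]
    counts = _nb_draw(rng, mean_matrix, spec.dispersion)

    truth = pd.DataFrame({"gene": genes, "is_de": lfc != 0, "log2fc": lfc})
    return CountSim(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=groups,
        truth=truth,
    )
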