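"""Particle extraction and calibrated morphometry.

The measurement pipeline mirrors a four-step image-processing sequence:
extract the cluster of interest from the segmented micrograph, convert it
to a weighted grayscale, binarise at a global threshold of 0.5, and run
Sobel edge detection for the boundary artifact. Particles are the
8-connected foreground components; each one is reported as a pixel-count
area and the axis lengths of its equivalent ellipse, both converted to
micrometres through the image calibration.

Conventions: coordinates are (row, col), 0-based, origin top-left;
orientation is in radians counter-clockwise from the +col axis. Second
central moments treat each pixel as a unit square, adding the 1/12
variance of a unit interval to the diagonal — the convention of the
classic image-processing toolbox ``regionprops``, under which a single
pixel has axis length 4*sqrt(1/12) ~ 1.1547 px rather than 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MEASUREMENT_COLUMNS, Micrograph
from .segmentation import Clustering, PEScore, flatten_image, run_kmeans, select_optimal_k

__all__ = [
    "AUTO",
    "GRAY_WEIGHTS",
    "ParticleMeasurement",
    "LabelledRegions",
    "extract_cluster",
    "resolve_auto_cluster",
    "to_grayscale",
    "binarize",
    "sobel_edges",
    "label_components",
    "fill_holes",
    "measure_particle",
    "measure_all",
    "analyze_micrograph",
    "MorphometryResult",
]

log = logging.getLogger(__name__)

#: Sentinel: pick the target cluster automatically (the cluster whose mean
#: grayscale differs most from that of the modal, largest-occupancy cluster).
AUTO = "auto"

#: BT.601 luma weights for the weighted R, G, B sum, normalised to sum to
#: exactly 1 so an achromatic pixel (v, v, v) maps to gray value v.
_W = (0.2989, 0.5870, 0.1140)
GRAY_WEIGHTS = tuple(w / sum(_W) for w in _W)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class LabelledRegions:
    """8-connected foreground components, labelled 1..R by decreasing size."""

    labels: np.ndarray        # (H, W) ints, 0 = background
    n_regions: int
    connectivity: int = 8

    def pixel_count(self, region_id: int) -> int:
        self._check(region_id)
        return int((self.labels == region_id).sum())

    def _check(self, region_id: int) -> None:
        if not 1 <= region_id <= self.n_regions:
            raise ValueError(f"region id {region_id} outside 1..{self.n_regions}")


@dataclass(frozen=True)
class ParticleMeasurement:
    particle_id: int
    pixel_count: int
    area_um2: float
    major_um: float
    minor_um: float
    centroid_px: tuple[float, float]     # (row, col)
    orientation_rad: float


def to_grayscale(m: Micrograph | np.ndarray) -> np.ndarray:
    """Weighted R/G/B sum (BT.601), values in [0, 1]."""
    pix = m.pixels if isinstance(m, Micrograph) else np.asarray(m, dtype=float)
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * pix[..., 0] + wg * pix[..., 1] + wb * pix[..., 2]
    return np.clip(gray, 0.0, 1.0)


def binarize(gray: np.ndarray, threshold: float = 0.5, particle_is_dark: bool = True) -> np.ndarray:
    """Global threshold. Dark-particle polarity marks gray < threshold as foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    gray = np.asarray(gray)
    return gray < threshold if particle_is_dark else gray >= threshold


def sobel_edges(gray: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2) with edge replication.

    Uses the standard 3x3 kernels; if the maximum magnitude exceeds 1 the
    map is rescaled by it so the output stays a valid [0, 1] image.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError(f"Sobel needs a 2-D image of at least 3 x 3, got shape {gray.shape}")
    gx = ndimage.sobel(gray, axis=1, mode="nearest")
    gy = ndimage.sobel(gray, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 1.0:
        mag = mag / peak
    return mag


def extract_cluster(m: Micrograph, c: Clustering, target_cluster) -> Micrograph:
    """Keep pixels of the target cluster, blacking out all others.

    ``target_cluster`` is a 1-based cluster id or :data:`AUTO`, which
    resolves to the cluster whose mean grayscale differs most from the
    modal cluster's mean (on a dark-particle/bright-background micrograph
    that is the particle cluster).
    """
    h, w = m.shape
    if c.n != h * w:
        raise ValueError("clustering does not match image size")
    if target_cluster == AUTO:
        target_cluster = resolve_auto_cluster(m, c)
    target_cluster = int(target_cluster)
    if not 1 <= target_cluster <= c.k:
        raise ValueError(f"cluster id {target_cluster} outside 1..{c.k}")
    mask = (c.labels == target_cluster).reshape(h, w)
    if not mask.any():
        warnings.warn(f"cluster {target_cluster} holds no pixels; extracted image is all black")
    out = np.where(mask[..., None], m.pixels, 0.0)
    return Micrograph(out, m.scale_um_per_px, m.magnification_tag, m.source_id)


def resolve_auto_cluster(m: Micrograph, c: Clustering) -> int:
    """Cluster whose mean gray level is farthest from the modal cluster's."""
    gray = to_grayscale(m).ravel()
    counts = np.bincount(c.labels - 1, minlength=c.k)
    modal = int(counts.argmax()) + 1
    means = np.full(c.k, np.nan)
    for j in range(1, c.k + 1):
        sel = gray[c.labels == j]
        if sel.size:
            means[j - 1] = sel.mean()
    diffs = np.abs(means - means[modal - 1])
    diffs[modal - 1] = -np.inf
    diffs = np.where(np.isnan(diffs), -np.inf, diffs)
    return int(diffs.argmax()) + 1


def label_components(mask: np.ndarray, min_pixels: int = 5) -> LabelledRegions:
    """8-connected components of the foreground, smallest-first pruned.

    Components with fewer than ``min_pixels`` pixels are discarded as
    noise; the survivors are renumbered 1..R by decreasing pixel count
    (ties broken by first occurrence in raster order).
    """
    mask = np.asarray(mask, dtype=bool)
    raw, n_raw = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n_raw == 0:
        return LabelledRegions(np.zeros_like(raw), 0)
    counts = np.bincount(raw.ravel())[1:]           # counts[i] = size of label i+1
    keep = np.where(counts >= min_pixels)[0]
    order = keep[np.argsort(-counts[keep], kind="stable")]
    relabel = np.zeros(n_raw + 1, dtype=raw.dtype)
    for new_id, old_idx in enumerate(order, start=1):
        relabel[old_idx + 1] = new_id
    return LabelledRegions(relabel[raw], len(order))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed background holes so area counts the particle footprint."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def measure_particle(regions: LabelledRegions, region_id: int, scale_um_per_px: float) -> ParticleMeasurement:
    """Area and equivalent-ellipse axis lengths of one labelled region.

    area_um2 = pixel_count * scale^2. The axis lengths come from the
    eigendecomposition of the second central moment matrix of the pixel
    coordinates with the +1/12 pixel-as-unit-square correction on the
    diagonal: major = 4*sqrt(lambda_max)*scale, minor =
    4*sqrt(lambda_min)*scale. Orientation is the principal-eigenvector
    angle, counter-clockwise from the +col axis.
    """
    regions._check(region_id)
    if scale_um_per_px <= 0:
        raise ValueError("scale_um_per_px must be positive")
    rows, cols = np.nonzero(regions.labels == region_id)
    n = rows.size
    r_mean, c_mean = rows.mean(), cols.mean()
    dr, dc = rows - r_mean, cols - c_mean
    mrr = dr @ dr / n + 1.0 / 12.0
    mcc = dc @ dc / n + 1.0 / 12.0
    mrc = dr @ dc / n
    mom = np.array([[mrr, mrc], [mrc, mcc]])
    evals, evecs = np.linalg.eigh(mom)        # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    v = evecs[:, 1]                           # principal axis, (row, col) components
    orientation = float(np.arctan2(-v[0], v[1]))
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    s = float(scale_um_per_px)
    return ParticleMeasurement(
        particle_id=region_id,
        pixel_count=n,
        area_um2=n * s * s,
        major_um=4.0 * np.sqrt(lam_max) * s,
        minor_um=4.0 * np.sqrt(max(lam_min, 0.0)) * s,
        centroid_px=(float(r_mean), float(c_mean)),
        orientation_rad=orientation,
    )


def measure_all(regions: LabelledRegions, scale_um_per_px: float, source_id: str = "") -> pd.DataFrame:
    """Measure every region, returning a table sorted by decreasing area."""
    rows = [measure_particle(regions, i, scale_um_per_px) for i in range(1, regions.n_regions + 1)]
    rows.sort(key=lambda p: -p.area_um2)
    df = pd.DataFrame(
        {
            "source_id": source_id,
            "particle_id": [p.particle_id for p in rows],
            "area_um2": [p.area_um2 for p in rows],
            "major_um": [p.major_um for p in rows],
            "minor_um": [p.minor_um for p in rows],
            "pixel_count": [p.pixel_count for p in rows],
            "centroid_row": [p.centroid_px[0] for p in rows],
            "centroid_col": [p.centroid_px[1] for p in rows],
            "orientation_rad": [p.orientation_rad for p in rows],
        }
    )
    return df


@dataclass
class MorphometryResult:
    """Full per-image analysis output."""

    measurements: pd.DataFrame
    k_star: int
    pe_scores: list[PEScore]
    target_cluster: int
    edge_map: np.ndarray
    labels: LabelledRegions


def analyze_micrograph(
    m: Micrograph,
    k_range=range(2, 7),
    seed: int = 0,
    threshold: float = 0.5,
    particle_is_dark: bool = True,
    min_pixels: int = 5,
    target_cluster=AUTO,
    fill: bool = True,
    max_iter: int = 100,
    restarts: int = 1,
    pe_variant: str = "occupancy",
) -> MorphometryResult:
    """Run the full segmentation-to-measurement pipeline on one micrograph.

    Stages: PE-based selection of k, k-means at the winning k, extraction
    of the target cluster (AUTO = most different from the modal cluster),
    weighted grayscale, global 0.5 threshold, optional hole filling,
    8-connected labelling, per-region morphometry. The binarised mask is
    intersected with the target-cluster membership so that the black fill
    outside the extracted cluster can never masquerade as foreground.
    The Sobel magnitude of the extracted grayscale is returned as the
    boundary diagnostic artifact. Rows are sorted by decreasing area; an
    image with no detectable particle yields an empty table.
    """
    k_star, scores = select_optimal_k(
        m, k_range=k_range, seed=seed, max_iter=max_iter, restarts=restarts, pe_variant=pe_variant
    )
    fs = flatten_image(m)
    clustering = run_kmeans(fs, k_star, seed=seed, max_iter=max_iter, restarts=restarts)
    if target_cluster == AUTO:
        target = resolve_auto_cluster(m, clustering)
        log.info("auto-selected cluster %d of %d", target, k_star)
    else:
        target = int(target_cluster)
    extracted = extract_cluster(m, clustering, target)
    gray = to_grayscale(extracted)
    edges = sobel_edges(gray)
    member = (clustering.labels == target).reshape(m.shape)
    mask = binarize(gray, threshold=threshold, particle_is_dark=particle_is_dark) & member
    if fill:
        mask = fill_holes(mask)
    regions = label_components(mask, min_pixels=min_pixels)
    table = measure_all(regions, m.scale_um_per_px, source_id=m.source_id)
    return MorphometryResult(
        measurements=table,
        k_star=k_star,
        pe_scores=scores,
        target_cluster=target,
        edge_map=edges,
        labels=regions,
    )
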