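"""Automated cell segmentation by correlation clustering of neighboring pixels.

The algorithm treats every pixel as a singleton region and greedily merges
the pair of 4-connected neighboring regions with the highest Pearson signal
correlation; the merged region's signal is the average of the two merged
signals, and correlations with its neighbors are recomputed exactly.  After
a fixed number of merges ``I`` (25,000 for a 256 x 256 field, scaled
proportionally with pixel count otherwise), candidate regions are filtered by
size, dispersion (roundness) and a border-weight ratio, after per-pixel
weights have been estimated by an iterative rank-1 ("common signal") scheme.

Clustering operates on preprocessed signals: temporally binned (30 s bins),
high-pass filtered (100 s cutoff period) and with each pixel's projection
onto the global mean signal removed, so that shared slow drifts and global
fluctuations do not drive the merges.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import Movie


@dataclass
class SegmentationParams:
    """Knobs of the segmentation stage.

    stop_iteration: number of greedy merges; ``None`` scales the reference
        value of 25,000 (tuned for 256 x 256 = 65,536 pixels) by pixel count.
    bin_seconds: temporal bin used for clustering correlations.
    highpass_period: cutoff period (s) of the slow-drift removal filter.
    minsize/maxsize: retained-region pixel-count bounds.
    maxdisp: upper bound on mean squared pixel distance from the region
        center divided by region size (selects round regions).
    maxborder: upper bound on (mean border-pixel weight)/(mean pixel weight).
    weight_iterations: iterations of the pixel-weight estimation scheme.
    """

    stop_iteration: int | None = None
    bin_seconds: float = 30.0
    highpass_period: float = 100.0
    minsize: int = 10
    maxsize: int = 200
    maxdisp: float = 0.5
    maxborder: float = 0.9
    weight_iterations: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.minsize < self.maxsize:
            raise ValueError("require 0 < minsize < maxsize")
        if self.maxdisp <= 0:
            raise ValueError("maxdisp must be positive")
        if not 0 < self.maxborder <= 1:
            raise ValueError("maxborder must be in (0, 1]")

    def resolve_stop_iteration(self, n_pixels: int) -> int:
        if self.stop_iteration is not None:
            return self.stop_iteration
        return int(round(25_000 * n_pixels / (256 * 256)))


@dataclass
class PixelSignals:
    """Per-pixel time series (rows = time, columns = pixels, row-major)."""

    signals: np.ndarray                 # (n_samples, n_pixels)
    image_shape: tuple[int, int]

    @property
    def n_pixels(self) -> int:
        return self.signals.shape[1]


@dataclass
class RegionSet:
    """Segmentation output: label image, per-region pixels/weights, history.

    Label 0 marks unassigned / neuropil pixels; region ids are 1-based.
    """

    labels: np.ndarray                          # (rows, cols) int
    pixels: dict[int, tuple[np.ndarray, np.ndarray]]
    weights: dict[int, np.ndarray] = field(default_factory=dict)
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.pixels)

    def size(self, region_id: int) -> int:
        return len(self.pixels[region_id][0])

    def mask(self, region_id: int) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        rr, cc = self.pixels[region_id]
        m[rr, cc] = True
        return m


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def signals_from_movie(movie: Movie) -> PixelSignals:
    """Raw full-rate pixel time courses."""
    t, r, c = movie.shape
    return PixelSignals(signals=movie.data.reshape(t, r * c).astype(float),
                        image_shape=(r, c))


def preprocess_full_rate(movie: Movie, params: SegmentationParams
                         ) -> PixelSignals:
    """Full-rate signals with the same large-scale-correlation removal.

    Weight estimation needs each region's own common signal to dominate, so
    slow drifts (high-pass, 100 s cutoff period) and the global mean signal
    (projection subtraction) are removed as for clustering, but without
    temporal binning.
    """
    t, r, c = movie.shape
    x = movie.data.reshape(t, r * c).astype(float)
    cutoff = 1.0 / params.highpass_period
    if t > 30 and cutoff < movie.frame_rate / 2:
        sos = sps.butter(1, cutoff, btype="highpass", fs=movie.frame_rate,
                         output="sos")
        x = sps.sosfiltfilt(sos, x, axis=0)
    else:
        x = x - x.mean(axis=0, keepdims=True)
    g = x.mean(axis=1)
    g2 = float(g @ g)
    if g2 > 0:
        x = x - np.outer(g, (g @ x) / g2)
    return PixelSignals(signals=x, image_shape=(r, c))


def preprocess_for_clustering(movie: Movie, params: SegmentationParams
                              ) -> PixelSignals:
    """Bin, high-pass filter and remove the global-signal projection."""
    if movie.duration_s < 2 * params.highpass_period:
        warnings.warn("movie shorter than twice the high-pass period; "
                      "slow-drift removal will be approximate", stacklevel=2)
    frames_per_bin = max(1, int(round(params.bin_seconds * movie.frame_rate)))
    t, r, c = movie.shape
    n_bins = t // frames_per_bin
    if n_bins < 1:
        raise ValueError("movie shorter than one temporal bin")
    x = movie.data[:n_bins * frames_per_bin].reshape(
        n_bins, frames_per_bin, r * c).mean(axis=1)

    # high-pass: remove slow components with period > highpass_period
    fs = 1.0 / params.bin_seconds
    cutoff = 1.0 / params.highpass_period
    if n_bins > 9 and cutoff < fs / 2:
        sos = sps.butter(1, cutoff, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=0)
    else:
        x = x - x.mean(axis=0, keepdims=True)

    # remove each pixel's projection onto the global mean signal
    g = x.mean(axis=1)
    g2 = float(g @ g)
    if g2 > 0:
        x = x - np.outer(g, (g @ x) / g2)
    return PixelSignals(signals=x, image_shape=(r, c))


# --------------------------------------------------------------------------
# greedy correlation clustering
# --------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; -inf if either signal has zero variance (merged last)."""
    a = a - a.mean()
    b = b - b.mean()
    na = float(a @ a)
    nb = float(b @ b)
    if na <= 0 or nb <= 0:
        return -np.inf
    return float(np.clip((a @ b) / np.sqrt(na * nb), -1.0, 1.0))


def cluster_pixels(signals: PixelSignals, params: SegmentationParams
                   ) -> RegionSet:
    """Perform exactly ``I`` greedy merges of neighboring pixels/regions.

    Ties in correlation are broken by the lowest (row, col) lexicographic
    order of the two regions' minimum pixels, which makes the procedure
    deterministic and independent of pixel storage order.
    """
    x = np.asarray(signals.signals, dtype=float)
    rows, cols = signals.image_shape
    n_pix = rows * cols
    if n_pix < 2:
        raise ValueError("need at least two pixels")
    if not np.all(np.isfinite(x)):
        raise ValueError("signals must be finite")
    n_merges = params.resolve_stop_iteration(n_pix)
    if n_merges >= n_pix - 1:
        raise ValueError(
            f"stop_iteration={n_merges} >= n_pixels-1={n_pix - 1}: "
            "clustering cannot exceed a full merge")

    # region state, keyed by representative = min flat pixel index
    sig: dict[int, np.ndarray] = {i: x[:, i] for i in range(n_pix)}
    members: dict[int, list[int]] = {i: [i] for i in range(n_pix)}
    neighbors: dict[int, set[int]] = {i: set() for i in range(n_pix)}
    for i in range(n_pix):
        r, c = divmod(i, cols)
        if c + 1 < cols:
            neighbors[i].add(i + 1)
            neighbors[i + 1].add(i)
        if r + 1 < rows:
            neighbors[i].add(i + cols)
            neighbors[i + cols].add(i)

    version = np.zeros(n_pix, dtype=np.int64)
    heap: list[tuple[float, int, int, int, int]] = []

    def push(a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        r = _pearson(sig[a], sig[b])
        heapq.heappush(heap, (-r, a, b, version[a], version[b]))

    for i in range(n_pix):
        for j in neighbors[i]:
            if j > i:
                push(i, j)

    history: list[tuple[int, int, float]] = []
    merges_done = 0
    while merges_done < n_merges:
        neg_r, a, b, va, vb = heapq.heappop(heap)
        if a not in sig or b not in sig:
            continue
        if version[a] != va or version[b] != vb:
            continue
        if b not in neighbors[a]:
            continue
        corr = -neg_r if np.isfinite(neg_r) else -np.inf
        # merge b into a (a < b, so representative stays the min pixel)
        sig[a] = 0.5 * (sig[a] + sig[b])
        members[a].extend(members.pop(b))
        nbrs = (neighbors[a] | neighbors.pop(b)) - {a, b}
        for n in nbrs:
            neighbors[n].discard(b)
            neighbors[n].add(a)
        neighbors[a] = nbrs
        del sig[b]
        version[a] += 1
        history.append((a, b, corr))
        for n in nbrs:
            push(a, n)
        merges_done += 1

    labels = np.zeros((rows, cols), dtype=np.int32)
    pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for new_id, rep in enumerate(sorted(members), start=1):
        flat = np.sort(np.array(members[rep], dtype=int))
        rr, cc = flat // cols, flat % cols
        labels[rr, cc] = new_id
        pixels[new_id] = (rr, cc)
    return RegionSet(labels=labels, pixels=pixels, merge_history=history)


# --------------------------------------------------------------------------
# pixel weights
# --------------------------------------------------------------------------

def compute_region_weights(x: np.ndarray, n_iterations: int = 3) -> np.ndarray:
    """Estimate per-pixel contributions to a region's common signal.

    ``x`` holds the region's pixel time courses as columns (T, N).  Weights
    start uniform at 1/N; each iteration recomputes the region signal
    x_reg = X w and then regresses every pixel time course onto it,
    w_i <- <x_i, x_reg> / ||x_reg||^2, renormalizing to sum 1.  This is a
    power iteration toward the dominant rank-1 component of X, so pixels
    whose signal amplitude is low (e.g. nuclei, mask edges) receive small
    weights.  Degenerate (zero-signal) regions keep uniform weights.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("x must be (n_samples, n_pixels) with >= 1 pixel")
    n = x.shape[1]
    xc = x - x.mean(axis=0, keepdims=True)
    w = np.full(n, 1.0 / n)
    for _ in range(n_iterations):
        x_reg = xc @ w
        denom = float(x_reg @ x_reg)
        if denom <= 0:
            break
        w = (xc.T @ x_reg) / denom
        s = w.sum()
        if s < 0:
            w, s = -w, -s
        if abs(s) < 1e-12:
            w = np.full(n, 1.0 / n)
            break
        w = w / s
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("non-finite weights")
    return w


def attach_weights(regions: RegionSet, raw: PixelSignals,
                   params: SegmentationParams) -> None:
    """Compute weights (in place) for every region within the size bounds."""
    cols = regions.labels.shape[1]
    for rid, (rr, cc) in regions.pixels.items():
        if params.minsize <= len(rr) <= params.maxsize:
            x = raw.signals[:, rr * cols + cc]
            regions.weights[rid] = compute_region_weights(
                x, params.weight_iterations)


# --------------------------------------------------------------------------
# region selection
# --------------------------------------------------------------------------

def region_dispersion(rr: np.ndarray, cc: np.ndarray) -> float:
    """Mean squared distance to the centroid divided by region size.

    Dimensionless roundness measure: ~1/(2 pi) = 0.16 for a filled disk,
    growing linearly with length for a 1-pixel-wide line.
    """
    pts = np.column_stack([rr, cc]).astype(float)
    center = pts.mean(axis=0)
    return float(((pts - center) ** 2).sum(axis=1).mean() / len(pts))


def border_pixel_mask(rr: np.ndarray, cc: np.ndarray,
                      shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask over region pixels that touch an out-of-region pixel."""
    inside = np.zeros(shape, dtype=bool)
    inside[rr, cc] = True
    border = np.zeros(len(rr), dtype=bool)
    for k, (r, c) in enumerate(zip(rr, cc)):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < shape[0] and 0 <= nc < shape[1] and not inside[nr, nc]:
                border[k] = True
                break
    return border


def select_neuronal_regions(regions: RegionSet, params: SegmentationParams,
                            include: set[int] | None = None,
                            exclude: set[int] | None = None) -> RegionSet:
    """Keep regions with neuron-like size, roundness and weight profile.

    A region is retained iff minsize <= size <= maxsize, dispersion <
    maxdisp, and (mean border-pixel weight)/(mean pixel weight) < maxborder.
    ``include``/``exclude`` are optional region-id lists standing in for the
    interactive curation step of a live rig.
    """
    include = include or set()
    exclude = exclude or set()
    kept: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for rid, (rr, cc) in regions.pixels.items():
        if rid in exclude:
            continue
        if rid not in include:
            size = len(rr)
            if not params.minsize <= size <= params.maxsize:
                continue
            if region_dispersion(rr, cc) >= params.maxdisp:
                continue
            if rid not in regions.weights:
                raise ValueError(f"region {rid} has no weights; "
                                 "run attach_weights first")
            w = regions.weights[rid]
            border = border_pixel_mask(rr, cc, regions.labels.shape)
            mean_all = w.mean()
            if mean_all == 0:
                continue
            if border.any() and w[border].mean() / mean_all >= params.maxborder:
                continue
        kept[rid] = (rr, cc)

    labels = np.zeros_like(regions.labels)
    pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    weights: dict[int, np.ndarray] = {}
    for new_id, rid in enumerate(sorted(kept), start=1):
        rr, cc = kept[rid]
        labels[rr, cc] = new_id
        pixels[new_id] = (rr, cc)
        if rid in regions.weights:
            weights[new_id] = regions.weights[rid]
    return RegionSet(labels=labels, pixels=pixels, weights=weights,
                     merge_history=list(regions.merge_history))


# --------------------------------------------------------------------------
# convenience & validation
# --------------------------------------------------------------------------

def segment_movie(movie: Movie, params: SegmentationParams) -> RegionSet:
    """Full segmentation: preprocess, cluster, weight, select."""
    clustered = cluster_pixels(preprocess_for_clustering(movie, params),
                               params)
    attach_weights(clustered, preprocess_full_rate(movie, params), params)
    return select_neuronal_regions(clustered, params)


def match_regions_to_masks(regions: RegionSet,
                           masks: list[tuple[np.ndarray, np.ndarray]],
                           shape: tuple[int, int]) -> np.ndarray:
    """Best intersection-over-union of each ground-truth mask with a region."""
    cols = shape[1]
    region_sets = {rid: set((rr * cols + cc).tolist())
                   for rid, (rr, cc) in regions.pixels.items()}
    ious = np.zeros(len(masks))
    for k, (rr, cc) in enumerate(masks):
        mask_set = set((np.asarray(rr) * cols + np.asarray(cc)).tolist())
        best = 0.0
        for pix in region_sets.values():
            inter = len(mask_set & pix)
            if inter:
                best = max(best, inter / len(mask_set | pix))
        ious[k] = best
    return ious
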