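"""Foci detection and nearest-neighbour spacing statistics.

Detects marker-defined foci in large colonies, summarises their
nearest-neighbour (NN) distance distribution with a fixed-bin histogram,
Shannon entropy and base-2 Jensen–Shannon divergence, and tests
non-randomness against Monte-Carlo nulls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import jensenshannon

from .colony_quant import ColonySet, otsu_threshold
from .errors import AnalysisError, ConfigurationError, InputError
from .synthetic_colonies import PatternSpec, generate_point_pattern

__all__ = [
    "PointPattern",
    "NNStats",
    "detect_foci",
    "nn_distances",
    "compare_distributions",
    "mc_test",
]

DEFAULT_N_BINS = 20


@dataclass(frozen=True)
class PointPattern:
    """Colony-relative point pattern on a disk."""

    points: np.ndarray              # (n, 2) μm
    radius: float                   # domain radius (μm)
    source: str = "observed"        # observed | random | rd-model | jittered-hex

    def validate(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("radius must be > 0")
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ConfigurationError("points must be an (n, 2) array")
        if len(pts) and np.hypot(pts[:, 0], pts[:, 1]).max() > self.radius * (1 + 1e-9):
            raise ConfigurationError("all points must lie within the domain radius")


@dataclass(frozen=True)
class NNStats:
    """Nearest-neighbour distance summary of a point pattern."""

    distances: np.ndarray           # per-point NN distance (μm)
    bin_edges: np.ndarray           # histogram bins (μm)
    hist: np.ndarray                # normalized histogram (probabilities)
    entropy_bits: float
    jsd_bits: float | None = None
    p_value: float | None = None
    n_null: int | None = None


def detect_foci(colony_set: ColonySet, channel: str, polarity: str = "negative",
                min_area: float = 2000.0, grid_h: float = 25.0,
                edge_exclude: float = 0.05) -> list[PointPattern]:
    """Detect marker-defined foci per kept colony.

    Cells are thresholded by Otsu on the pooled log-intensity; cells on
    the selected side (``polarity="negative"`` → below threshold) are
    rasterized onto a grid of spacing ``grid_h`` and grouped by
    8-connected components.  Components smaller than ``min_area`` (μm²)
    or touching the outer ``edge_exclude`` fraction of the radius are
    dropped; the survivors' centroids form the pattern.
    """
    if polarity not in ("negative", "positive"):
        raise ConfigurationError("polarity must be 'negative' or 'positive'")
    if grid_h <= 0 or min_area < 0:
        raise ConfigurationError("grid_h must be > 0 and min_area >= 0")
    if channel not in colony_set.cells.columns:
        raise InputError(f"channel {channel!r} not in cells table")
    kept = colony_set.kept_ids()
    if len(kept) == 0:
        raise AnalysisError("no kept colonies")
    pooled = colony_set.cells[colony_set.cells["colony"].isin(set(kept))]
    logv = np.log(np.maximum(pooled[channel].to_numpy(dtype=float), 1e-12))
    thr = otsu_threshold(logv)
    patterns = []
    for cid in kept:
        sub = colony_set.cells[colony_set.cells["colony"] == cid]
        R = float(colony_set.colonies.loc[
            colony_set.colonies["colony"] == cid, "radius_eff"].iloc[0])
        lv = np.log(np.maximum(sub[channel].to_numpy(dtype=float), 1e-12))
        sel = lv < thr if polarity == "negative" else lv >= thr
        x = sub["rel_x"].to_numpy(dtype=float)[sel]
        y = sub["rel_y"].to_numpy(dtype=float)[sel]
        m = int(math.ceil(2 * R / grid_h)) + 1
        img = np.zeros((m, m), dtype=bool)
        ix = np.clip(((x + R) / grid_h).astype(int), 0, m - 1)
        iy = np.clip(((y + R) / grid_h).astype(int), 0, m - 1)
        img[iy, ix] = True
        labels, n_comp = ndimage.label(img, structure=np.ones((3, 3), dtype=int))
        pts = []
        for lab in range(1, n_comp + 1):
            yy, xx = np.nonzero(labels == lab)
            area = len(yy) * grid_h ** 2
            if area < min_area:
                continue
            px = (xx + 0.5) * grid_h - R
            py = (yy + 0.5) * grid_h - R
            if np.hypot(px, py).max() > (1.0 - edge_exclude) * R:
                continue
            pts.append([px.mean(), py.mean()])
        pattern = PointPattern(points=np.array(pts) if pts else np.empty((0, 2)),
                               radius=R, source="observed")
        patterns.append(pattern)
    return patterns


def nn_distances(pattern: PointPattern, n_bins: int = DEFAULT_N_BINS) -> NNStats:
    """NN distances, fixed-bin histogram over [0, radius/2], and the
    Shannon entropy (bits) of the normalized histogram."""
    pattern.validate()
    pts = np.asarray(pattern.points, dtype=float)
    if len(pts) < 2:
        raise AnalysisError("nn_distances needs at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    dist = d[:, 1]
    edges = np.linspace(0.0, pattern.radius / 2.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(dist, edges[0], edges[-1] * (1 - 1e-12)),
                             bins=edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return NNStats(distances=dist, bin_edges=edges, hist=p, entropy_bits=entropy)


def _jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    return float(jensenshannon(p, q, base=2) ** 2)


def compare_distributions(obs: NNStats, ref: NNStats) -> float:
    """Base-2 Jensen–Shannon divergence between two NN histograms (bits)."""
    if obs.bin_edges.shape != ref.bin_edges.shape or \
            not np.allclose(obs.bin_edges, ref.bin_edges):
        raise InputError("NN histograms must share identical bin edges")
    return _jsd_bits(obs.hist, ref.hist)


def _batch_uniform_nn_hists(n_pat: int, n_pts: int, radius: float,
                            edges: np.ndarray, rng: np.random.Generator
                            ) -> np.ndarray:
    """Vectorized NN histograms of ``n_pat`` iid uniform disk patterns."""
    hists = np.empty((n_pat, len(edges) - 1))
    chunk = max(1, int(2e7 // max(n_pts * n_pts, 1)))
    hi = edges[-1] * (1 - 1e-12)
    for start in range(0, n_pat, chunk):
        b = min(chunk, n_pat - start)
        u = rng.random((b, n_pts))
        theta = rng.random((b, n_pts)) * 2 * math.pi
        r = radius * np.sqrt(u)
        pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)
        diff = pts[:, :, None, :] - pts[:, None, :, :]
        d2 = (diff ** 2).sum(-1)
        ii = np.arange(n_pts)
        d2[:, ii, ii] = np.inf
        nn = np.sqrt(d2.min(-1))
        for j in range(b):
            counts, _ = np.histogram(np.clip(nn[j], 0, hi), bins=edges)
            hists[start + j] = counts / counts.sum()
    return hists


def mc_test(obs: PointPattern, null_kind: str = "uniform-random",
            n_null: int = 999, seed: int = 0,
            n_bins: int = DEFAULT_N_BINS) -> NNStats:
    """Monte-Carlo non-randomness test of a point pattern.

    Generates ``n_null`` null patterns with matched point count and
    domain, computes the pooled-null NN histogram, and uses
    JSD(pattern vs pooled null) as the statistic:
    p = (1 + #{JSD_null_i ≥ JSD_obs}) / (n_null + 1).
    """
    if n_null < 99:
        raise ConfigurationError("n_null must be >= 99")
    stats_obs = nn_distances(obs, n_bins=n_bins)
    n_pts = len(obs.points)
    rng = np.random.default_rng(seed)
    edges = stats_obs.bin_edges
    if null_kind == "uniform-random":
        null_hists = _batch_uniform_nn_hists(n_null, n_pts, obs.radius, edges, rng)
    elif null_kind in ("jittered-hex", "rd-maxima"):
        # lattice spacing chosen so the clipped hex lattice holds >= n
        # points; patterns are subsampled to the matched count
        d = obs.radius * math.sqrt(2 * math.pi / (math.sqrt(3) * max(n_pts, 2)))
        null_hists = np.empty((n_null, n_bins))
        for i in range(n_null):
            spec = PatternSpec(kind=null_kind, n_points=n_pts, spacing=d,
                               jitter=0.05 * d, radius=obs.radius,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
            pts = generate_point_pattern(spec)
            attempts = 0
            while len(pts) < n_pts and null_kind == "jittered-hex":
                attempts += 1
                if attempts > 20:
                    raise AnalysisError(
                        "could not generate a matched-count null pattern")
                spec = PatternSpec(kind=null_kind, n_points=n_pts,
                                   spacing=spec.spacing * 0.95, jitter=0.05 * d,
                                   radius=obs.radius,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))
                pts = generate_point_pattern(spec)
            if len(pts) > n_pts:
                pts = pts[rng.choice(len(pts), n_pts, replace=False)]
            if len(pts) < 2:
                raise AnalysisError("null pattern generation produced < 2 points")
            null_hists[i] = nn_distances(
                PointPattern(points=pts, radius=obs.radius, source=null_kind),
                n_bins=n_bins).hist
    else:
        raise ConfigurationError(f"unknown null kind {null_kind!r}")
    pooled = null_hists.mean(axis=0)
    pooled = pooled / pooled.sum()
    jsd_obs = _jsd_bits(stats_obs.hist, pooled)
    jsd_null = np.array([_jsd_bits(h, pooled) for h in null_hists])
    p = (1.0 + np.sum(jsd_null >= jsd_obs)) / (n_null + 1.0)
    return replace(stats_obs, jsd_bits=jsd_obs, p_value=float(p), n_null=n_null)
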