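"""Single-cell colony quantification.

Re-implements the plate-level analysis chain: DBSCAN colony assignment
with noise rejection, colony QC filtering, centroid-relative coordinates,
annular radial profiles with SD and t-based 95% confidence intervals,
hexagonal-bin expression maps, and per-colony percent-positive
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN
from sklearn.mixture import GaussianMixture

from .errors import AnalysisError, ConfigurationError, InputError

__all__ = [
    "ColonySet",
    "RadialProfile",
    "HexMap",
    "assign_colonies",
    "dbscan_reference",
    "filter_colonies",
    "radial_profile",
    "hex_map",
    "percent_positive",
    "otsu_threshold",
]


@dataclass
class ColonySet:
    """Per-cell colony labels plus per-colony summaries.

    ``cells`` is a copy of the input table with added columns ``colony``
    (global 0-based id, −1 = noise), ``rel_x``, ``rel_y`` (centroid-
    relative μm) and ``r_norm`` (radius / effective colony radius).
    ``colonies`` has one row per colony: centroid, member count,
    effective radius (95th percentile of member radii) and a kept flag.
    """

    cells: pd.DataFrame
    colonies: pd.DataFrame

    def kept_ids(self) -> np.ndarray:
        return self.colonies.loc[self.colonies["kept"], "colony"].to_numpy()


def _median_nn_spacing(xy: np.ndarray) -> float:
    d, _ = cKDTree(xy).query(xy, k=2)
    return float(np.median(d[:, 1]))


def assign_colonies(cells: pd.DataFrame, eps: float | None = None,
                    min_samples: int = 10) -> ColonySet:
    """Assign cells to colonies with DBSCAN, per well.

    ``eps`` defaults to 3× the median nearest-neighbour spacing of each
    well.  Unclustered cells get label −1 (noise).
    """
    if eps is not None and eps <= 0:
        raise ConfigurationError("eps must be > 0")
    if min_samples < 2:
        raise ConfigurationError("min_samples must be >= 2")
    for col in ("well", "x", "y"):
        if col not in cells.columns:
            raise InputError(f"cells table lacks required column {col!r}")
    out = cells.copy().reset_index(drop=True)
    out["colony"] = -1
    next_id = 0
    colony_rows = []
    for well, idx in out.groupby("well", sort=True).groups.items():
        idx = np.asarray(idx)
        xy = out.loc[idx, ["x", "y"]].to_numpy(dtype=float)
        if len(idx) < min_samples:
            raise InputError(
                f"well {well!r} has fewer cells ({len(idx)}) than min_samples")
        e = eps if eps is not None else 3.0 * _median_nn_spacing(xy)
        labels = DBSCAN(eps=e, min_samples=min_samples).fit_predict(xy)
        for lab in np.unique(labels):
            if lab < 0:
                continue
            members = idx[labels == lab]
            out.loc[members, "colony"] = next_id
            cx, cy = out.loc[members, ["x", "y"]].mean()
            rr = np.hypot(out.loc[members, "x"] - cx, out.loc[members, "y"] - cy)
            # 95th percentile of member radii, debiased for uniform disk
            # coverage (the 95th percentile of r on a uniform disk of
            # radius R is R*sqrt(0.95))
            r_eff = float(np.percentile(rr, 95) / np.sqrt(0.95))
            colony_rows.append([next_id, well, cx, cy, len(members), r_eff, True])
            next_id += 1
    colonies = pd.DataFrame(colony_rows, columns=[
        "colony", "well", "cx", "cy", "n", "radius_eff", "kept"])
    out["rel_x"] = np.nan
    out["rel_y"] = np.nan
    out["r_norm"] = np.nan
    for _, row in colonies.iterrows():
        m = out["colony"] == row["colony"]
        out.loc[m, "rel_x"] = out.loc[m, "x"] - row["cx"]
        out.loc[m, "rel_y"] = out.loc[m, "y"] - row["cy"]
        rad = max(row["radius_eff"], 1e-12)
        out.loc[m, "r_norm"] = np.hypot(out.loc[m, "rel_x"], out.loc[m, "rel_y"]) / rad
    return ColonySet(cells=out, colonies=colonies)


def dbscan_reference(xy: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Brute-force DBSCAN: neighbour graph at radius eps, core points =
    degree ≥ min_samples − 1, clusters = connected components over core
    points, border points attached to the lowest-numbered reaching
    cluster.  Cluster numbering follows ascending minimum core index, the
    same order scikit-learn produces.
    """
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps ** 2
    degree = adj.sum(1)            # includes self
    core = degree >= min_samples   # degree-1 >= min_samples-1
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        # breadth-first expansion over core points
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in np.nonzero(adj[j])[0]:
                if labels[k] < 0:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


def filter_colonies(colony_set: ColonySet, nominal_diameter: float,
                    count_bounds: tuple[float, float] = (0.5, 1.5),
                    radius_tol: float = 0.3,
                    expected_count: float | None = None) -> ColonySet:
    """Flag colonies whose member count or radius departs from the nominal
    geometry; flagged colonies are kept in the table with ``kept=False``.
    """
    if nominal_diameter <= 0:
        raise ConfigurationError("nominal_diameter must be > 0")
    colonies = colony_set.colonies.copy()
    if len(colonies) == 0:
        return ColonySet(cells=colony_set.cells, colonies=colonies)
    expected = expected_count if expected_count is not None \
        else float(colonies["n"].median())
    lo, hi = count_bounds
    r_nom = nominal_diameter / 2.0
    kept = (colonies["n"].between(lo * expected, hi * expected)
            & colonies["radius_eff"].between((1 - radius_tol) * r_nom,
                                             (1 + radius_tol) * r_nom))
    colonies["kept"] = kept.to_numpy()
    return ColonySet(cells=colony_set.cells, colonies=colonies)


@dataclass
class RadialProfile:
    """Annular radial profile across kept colonies (colonies weighted
    equally, not cells)."""

    bin_edges: np.ndarray           # normalized radius, partition of [0, 1]
    colony_means: np.ndarray        # (n_colonies, n_bins), NaN = empty bin
    mean: np.ndarray                # grand mean per bin
    sd: np.ndarray                  # SD across colonies (0 when n = 1)
    ci95: np.ndarray                # t-based 95% CI half-width
    n_colonies: np.ndarray          # colonies contributing per bin


def radial_profile(colony_set: ColonySet, channel: str,
                   n_bins: int = 10) -> RadialProfile:
    """Per-colony annular means on normalized radius, then grand mean, SD
    and 95% t-CI across colonies."""
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    if channel not in colony_set.cells.columns:
        raise InputError(f"channel {channel!r} not in cells table")
    kept = colony_set.kept_ids()
    if len(kept) == 0:
        raise AnalysisError("no kept colonies")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    means = np.full((len(kept), n_bins), np.nan)
    for i, cid in enumerate(kept):
        sub = colony_set.cells[colony_set.cells["colony"] == cid]
        rn = np.clip(sub["r_norm"].to_numpy(dtype=float), 0.0, 1.0)
        v = sub[channel].to_numpy(dtype=float)
        idx = np.clip(np.searchsorted(edges, rn, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                means[i, b] = v[sel].mean()
    n_col = np.sum(~np.isnan(means), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmean(means, axis=0)
        sd = np.nanstd(means, axis=0, ddof=1)
    sd = np.where(n_col >= 2, sd, 0.0)
    ci = np.zeros(n_bins)
    for b in range(n_bins):
        if n_col[b] >= 2:
            tcrit = stats.t.ppf(0.975, n_col[b] - 1)
            ci[b] = tcrit * sd[b] / np.sqrt(n_col[b])
    return RadialProfile(bin_edges=edges, colony_means=means, mean=grand,
                         sd=sd, ci95=ci, n_colonies=n_col)


@dataclass
class HexMap:
    """Hexagonal-bin mean expression map in centroid-relative coordinates."""

    centres: np.ndarray             # (n_hex, 2) hexagon centres (μm)
    mean: np.ndarray                # mean intensity per hexagon
    norm: np.ndarray                # min–max normalized mean ∈ [0, 1]
    counts: np.ndarray              # cells per hexagon


def _hex_bin_index(x: np.ndarray, y: np.ndarray, width: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Axial hex binning (pointy-top, flat-to-flat width ``width``).
    Returns integer axial indices (q, r) per point."""
    size = width / np.sqrt(3.0)
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    # cube rounding
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx, dy, dz = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def _hex_centre(q: np.ndarray, r: np.ndarray, width: float
                ) -> tuple[np.ndarray, np.ndarray]:
    size = width / np.sqrt(3.0)
    x = size * np.sqrt(3.0) * (q + r / 2.0)
    y = size * 1.5 * r
    return x, y


def hex_map(colony_set: ColonySet, channel: str, hex_width: float = 25.0
            ) -> HexMap:
    """Pool centroid-relative cells of kept colonies and average per
    hexagonal bin; min–max normalize across hexagons (all-equal → 0)."""
    if hex_width <= 0:
        raise ConfigurationError("hex_width must be > 0")
    if channel not in colony_set.cells.columns:
        raise InputError(f"channel {channel!r} not in cells table")
    kept = set(colony_set.kept_ids())
    if not kept:
        raise AnalysisError("no kept colonies")
    sub = colony_set.cells[colony_set.cells["colony"].isin(kept)]
    x = sub["rel_x"].to_numpy(dtype=float)
    y = sub["rel_y"].to_numpy(dtype=float)
    v = sub[channel].to_numpy(dtype=float)
    q, r = _hex_bin_index(x, y, hex_width)
    key = pd.DataFrame({"q": q, "r": r, "v": v})
    agg = key.groupby(["q", "r"], sort=True)["v"].agg(["mean", "count"]).reset_index()
    cx, cy = _hex_centre(agg["q"].to_numpy(), agg["r"].to_numpy(), hex_width)
    means = agg["mean"].to_numpy()
    rng_ = means.max() - means.min()
    norm = (means - means.min()) / rng_ if rng_ > 0 else np.zeros_like(means)
    return HexMap(centres=np.column_stack([cx, cy]), mean=means, norm=norm,
                  counts=agg["count"].to_numpy())


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance over histogram
    splits.  Returns the upper edge of the last bin of the lower class, so
    that ``values <= threshold`` reproduces the optimal split exactly."""
    values = np.asarray(values, dtype=float)
    hist, edges = np.histogram(values, bins=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        raise AnalysisError("otsu_threshold got no values")
    if values.min() == values.max():
        raise AnalysisError("otsu_threshold needs non-constant values")
    w0 = np.cumsum(w)
    w1 = total - w0
    m = np.cumsum(w * centres)
    mu0 = np.where(w0 > 0, m / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(w1 > 0, (m[-1] - m) / np.where(w1 > 0, w1, 1.0), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # exclude degenerate splits with an empty class
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return float(edges[int(np.argmax(between)) + 1])


def percent_positive(colony_set: ColonySet, channel: str,
                     method: str = "otsu", threshold: float | None = None
                     ) -> tuple[pd.DataFrame, float]:
    """Per-colony percent of cells above a threshold.

    ``method``: ``"fixed"`` (uses ``threshold``), ``"otsu"`` (Otsu on
    pooled log-intensity) or ``"gmm"`` (two-component Gaussian mixture on
    log-intensity; positive = upper-component posterior > 0.5).  Degenerate
    channels (zero variance) fall back to the fixed method with a warning.
    Returns (per-colony table, threshold used in intensity units).
    """
    if channel not in colony_set.cells.columns:
        raise InputError(f"channel {channel!r} not in cells table")
    kept = colony_set.kept_ids()
    if len(kept) == 0:
        raise AnalysisError("no kept colonies")
    sub = colony_set.cells[colony_set.cells["colony"].isin(set(kept))]
    vals = sub[channel].to_numpy(dtype=float)
    logv = np.log(np.maximum(vals, 1e-12))
    if method != "fixed" and np.ptp(logv) == 0:
        warnings.warn("degenerate channel (zero variance): falling back to "
                      "fixed threshold", stacklevel=2)
        method = "fixed"
        if threshold is None:
            threshold = float(vals[0]) + 1.0   # everything negative
    if method == "fixed":
        if threshold is None:
            raise ConfigurationError("fixed method requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        thr = float(np.exp(otsu_threshold(logv)))
    elif method == "gmm":
        gm = GaussianMixture(n_components=2, random_state=0, n_init=5)
        gm.fit(logv.reshape(-1, 1))
        upper = int(np.argmax(gm.means_.ravel()))
        post = gm.predict_proba(logv.reshape(-1, 1))[:, upper]
        # threshold = intensity midway between the points closest to the
        # posterior boundary; report it, but classify by posterior
        pos_mask = post > 0.5
        rows = []
        for cid in kept:
            sel = sub["colony"] == cid
            rows.append([cid, 100.0 * pos_mask[sel.to_numpy()].mean()])
        if pos_mask.any() and (~pos_mask).any():
            thr = float(np.exp(0.5 * (logv[pos_mask].min() + logv[~pos_mask].max())))
        else:
            thr = float(np.exp(logv.min()))
        return (pd.DataFrame(rows, columns=["colony", "pct_positive"]), thr)
    else:
        raise ConfigurationError(f"unknown threshold method {method!r}")
    rows = []
    for cid in kept:
        sel = sub[sub["colony"] == cid]
        rows.append([cid, 100.0 * (sel[channel].to_numpy() > thr).mean()])
    return pd.DataFrame(rows, columns=["colony", "pct_positive"]), thr
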