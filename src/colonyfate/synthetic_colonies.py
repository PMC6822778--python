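"""Seeded generators for synthetic inputs.

Three generators cover every downstream stage: per-cell plate tables
emulating micropatterned-colony immunofluorescence exports, reference
point patterns (uniform-random / jittered-hex / RD-model maxima), and
qPCR Ct tables with planted cluster structure.  Ground truth is emitted
as a separate sidecar table so the pipeline under test cannot consume it
by accident.  All randomness flows from a single integer seed through
``numpy.random.default_rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from . import rd_model

__all__ = [
    "ChannelModel",
    "PlateSpec",
    "PatternSpec",
    "QPCRSpec",
    "generate_plate",
    "generate_point_pattern",
    "generate_qpcr",
    "radial_profile_function",
]


# --------------------------------------------------------------------------
# named radial profiles
# --------------------------------------------------------------------------


def radial_profile_function(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """Named parametric radial mean profiles on normalized radius x = r/R."""
    profiles: dict[str, Callable[[np.ndarray], np.ndarray]] = {
        "flat": lambda x: np.ones_like(x),
        "peripheral-ring": lambda x: 0.2 + 0.8 * np.exp(-(x - 1.0) ** 2 / (2 * 0.15 ** 2)),
        "ramp": lambda x: x,
        "double-peak": lambda x: (0.3 + 0.7 * np.exp(-(x - 1.0) ** 2 / (2 * 0.12 ** 2))
                                  + 0.6 * np.exp(-x ** 2 / (2 * 0.25 ** 2))),
    }
    if name not in profiles:
        raise ConfigurationError(
            f"unknown profile {name!r}; choose from {sorted(profiles)}")
    return profiles[name]


@dataclass(frozen=True)
class ChannelModel:
    """Intensity model of one stain channel.

    ``profile`` is a named radial profile (see
    :func:`radial_profile_function`) or a callable of normalized radius.
    Per-cell intensity = gain · profile(r/R) · LogNormal(0, sigma) +
    background.  When ``positive_fraction`` is set the channel instead
    draws a Bernoulli positive/negative state per cell and emits two
    well-separated lognormal intensity modes (``neg_level``·gain and
    gain); the true state goes to the sidecar table.
    """

    profile: str | Callable[[np.ndarray], np.ndarray] = "flat"
    gain: float = 100.0
    sigma: float = 0.0
    background: float = 0.0
    positive_fraction: float | None = None
    neg_level: float = 0.05

    def profile_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        if callable(self.profile):
            return self.profile
        return radial_profile_function(self.profile)

    def validate(self) -> None:
        if self.gain < 0 or self.sigma < 0 or self.background < 0:
            raise ConfigurationError("gain, sigma and background must be >= 0")
        if self.positive_fraction is not None and not (0.0 <= self.positive_fraction <= 1.0):
            raise ConfigurationError("positive_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlateSpec:
    """Layout and intensity structure of a synthetic plate."""

    n_wells: int = 1
    colonies_per_well: int = 12
    colony_diameter: float = 500.0        # μm
    colony_pitch: float = 1000.0          # μm, centre-to-centre
    cell_density: float = 3500.0          # cells / mm²
    min_separation: float = 10.0          # μm hard-core radius
    off_colony_rate: float = 0.0          # cells / mm² outside colonies
    channel_models: Mapping[str, ChannelModel] = field(
        default_factory=lambda: {"ch_A": ChannelModel()})
    seed: int = 0

    def validate(self) -> None:
        if self.colony_pitch <= self.colony_diameter:
            raise ConfigurationError("colony_pitch must exceed colony_diameter")
        if self.n_wells < 1 or self.colonies_per_well < 1:
            raise ConfigurationError("need at least one well and one colony")
        if min(self.cell_density, self.off_colony_rate, self.min_separation) < 0:
            raise ConfigurationError("rates and separations must be >= 0")
        area_mm2 = math.pi * (self.colony_diameter / 2000.0) ** 2
        if self.cell_density * area_mm2 < 50:
            raise ConfigurationError(
                "cell_density too low: need >= 50 cells per colony")
        for cm in self.channel_models.values():
            cm.validate()


def _hard_core_disk(rng: np.random.Generator, R: float, target: int,
                    min_sep: float) -> np.ndarray:
    """Sequential hard-core sampling of ``target`` points in a disk of
    radius R; raises GenerationError if packing fails."""
    pts: list[tuple[float, float]] = []
    cell = max(min_sep, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    tries = 0
    max_tries = 200 * target + 1000
    while len(pts) < target:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"hard-core packing failed: placed {len(pts)}/{target} points "
                f"after {max_tries} tries (min_separation too large for density)")
        u, theta = rng.random(), rng.random() * 2 * math.pi
        r = R * math.sqrt(u)
        x, y = r * math.cos(theta), r * math.sin(theta)
        gx, gy = int(x // cell), int(y // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    px, py = pts[j]
                    if (px - x) ** 2 + (py - y) ** 2 < min_sep ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(pts))
            pts.append((x, y))
    return np.array(pts) if pts else np.empty((0, 2))


def generate_plate(spec: PlateSpec, seed: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-cell plate table and its ground-truth sidecar.

    Returns ``(cells, truth)``: ``cells`` has columns ``well, x, y`` plus
    one intensity column per channel; ``truth`` adds ``colony`` (0-based
    id, −1 off-colony), ``r_norm`` (NaN off-colony) and per-channel
    ``<ch>_true`` mean / ``<ch>_pos`` state columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    R = spec.colony_diameter / 2.0
    per_colony = int(round(spec.cell_density * math.pi * (R / 1000.0) ** 2))
    ncols = int(math.ceil(math.sqrt(spec.colonies_per_well)))
    well_w = ncols * spec.colony_pitch
    rows_cells, rows_truth = [], []
    colony_id = 0
    for w in range(spec.n_wells):
        well = f"W{w:02d}"
        centres = []
        for c in range(spec.colonies_per_well):
            ci, cj = divmod(c, ncols)
            centres.append(((cj + 0.5) * spec.colony_pitch,
                            (ci + 0.5) * spec.colony_pitch))
        for (cx, cy) in centres:
            pts = _hard_core_disk(rng, R, per_colony, spec.min_separation)
            rnorm = np.hypot(pts[:, 0], pts[:, 1]) / R
            for i in range(len(pts)):
                rows_cells.append([well, cx + pts[i, 0], cy + pts[i, 1]])
                rows_truth.append([colony_id, rnorm[i]])
            colony_id += 1
        # off-colony noise cells, kept clear of the colony discs
        n_rows = int(math.ceil(spec.colonies_per_well / ncols))
        well_h = n_rows * spec.colony_pitch
        n_off = rng.poisson(spec.off_colony_rate * well_w * well_h / 1e6)
        placed = 0
        guard = 0
        while placed < n_off:
            guard += 1
            if guard > 100 * n_off + 100:
                raise GenerationError("could not place off-colony cells")
            x, y = rng.random() * well_w, rng.random() * well_h
            if all((x - cx) ** 2 + (y - cy) ** 2 > (R + 2 * spec.min_separation) ** 2
                   for cx, cy in centres):
                rows_cells.append([well, x, y])
                rows_truth.append([-1, np.nan])
                placed += 1
    cells = pd.DataFrame(rows_cells, columns=["well", "x", "y"])
    truth = pd.DataFrame(rows_truth, columns=["colony", "r_norm"])
    truth.insert(0, "well", cells["well"])
    n = len(cells)
    for ch, cm in spec.channel_models.items():
        on_colony = truth["colony"].to_numpy() >= 0
        rn = np.nan_to_num(truth["r_norm"].to_numpy(), nan=0.0)
        noise = np.exp(rng.normal(0.0, cm.sigma, n)) if cm.sigma > 0 else np.ones(n)
        if cm.positive_fraction is not None:
            pos = rng.random(n) < cm.positive_fraction
            level = np.where(pos, 1.0, cm.neg_level)
            vals = cm.gain * level * noise + cm.background
            truth[f"{ch}_pos"] = pos & on_colony
            truth[f"{ch}_true"] = np.where(on_colony, cm.gain * level, 0.0)
        else:
            mean = cm.gain * cm.profile_fn()(rn)
            vals = mean * noise + cm.background
            truth[f"{ch}_true"] = np.where(on_colony, mean, 0.0)
        # off-colony cells carry background-level signal only
        vals = np.where(on_colony, vals,
                        cm.background + cm.gain * cm.neg_level *
                        (noise if cm.sigma > 0 else 1.0))
        cells[ch] = np.maximum(vals, 0.0)
    return cells, truth


# --------------------------------------------------------------------------
# point patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternSpec:
    """Specification of a reference point pattern on a disk."""

    kind: str = "uniform-random"     # uniform-random | jittered-hex | rd-maxima
    n_points: int = 30
    spacing: float = 100.0           # hex lattice spacing d (μm)
    jitter: float = 0.0              # Gaussian jitter sigma (μm)
    radius: float = 1500.0           # domain radius (μm)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("uniform-random", "jittered-hex", "rd-maxima"):
            raise ConfigurationError(f"unknown pattern kind {self.kind!r}")
        if self.radius <= 0:
            raise ConfigurationError("radius must be > 0")
        if self.kind == "uniform-random" and self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if self.kind == "jittered-hex" and self.spacing >= 2 * self.radius:
            raise GenerationError("lattice spacing exceeds domain diameter")


def _hex_lattice(d: float, R: float) -> np.ndarray:
    """Hexagonal lattice with spacing d clipped to the disk of radius R."""
    pts = []
    row_h = d * math.sqrt(3) / 2.0
    n_rows = int(R / row_h) + 1
    n_cols = int(R / d) + 1
    for i in range(-n_rows, n_rows + 1):
        y = i * row_h
        off = 0.5 * d if i % 2 else 0.0
        for j in range(-n_cols, n_cols + 1):
            x = j * d + off
            if x * x + y * y <= R * R:
                pts.append((x, y))
    return np.array(pts) if pts else np.empty((0, 2))


def generate_point_pattern(spec: PatternSpec, seed: int | None = None) -> np.ndarray:
    """Generate an (n, 2) array of point coordinates (μm, disk-centred)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.kind == "uniform-random":
        u = rng.random(spec.n_points)
        theta = rng.random(spec.n_points) * 2 * math.pi
        r = spec.radius * np.sqrt(u)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if spec.kind == "jittered-hex":
        pts = _hex_lattice(spec.spacing, spec.radius)
        if len(pts) < 2:
            raise GenerationError("lattice spacing leaves fewer than 2 points")
        if spec.jitter > 0:
            pts = pts + rng.normal(0.0, spec.jitter, pts.shape)
            inside = np.hypot(pts[:, 0], pts[:, 1]) <= spec.radius
            pts = pts[inside]
        return pts
    # rd-maxima: local maxima of a high-dose Turing simulation
    params = rd_model.default_params("turing")
    h = max(5.0, spec.radius / 100.0)
    domain = rd_model.build_domain("grid-2D", spec.radius, 1.2 * spec.radius, h)
    fields = rd_model.simulate(params, domain, T=48.0, save_every=48.0,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
    return rd_model.interior_maxima(fields[-1], domain)


# --------------------------------------------------------------------------
# qPCR tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QPCRSpec:
    """Planted-structure qPCR Ct table specification.

    ``planted_log2fc`` maps cluster name -> per-day log₂FC trajectory for
    days 1..len(traj); ``line_clusters`` maps line -> cluster name.
    """

    lines: Sequence[str] = ("L01", "L02", "L03")
    genes: Sequence[str] = ("GENE1",)
    days: Sequence[int] = (0, 1, 2, 3)
    replicates: int = 3
    planted_log2fc: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"Strong": (2.0, 3.0, 4.0),
                                 "Intermediate": (0.5, 1.0, 1.5),
                                 "Weak": (-1.0, -1.5, -2.0)})
    line_clusters: Mapping[str, str] = field(
        default_factory=lambda: {"L01": "Strong", "L02": "Intermediate",
                                 "L03": "Weak"})
    noise_sd: float = 0.0
    reference_gene: str = "GAPDH"
    reference_ct: float = 18.0
    baseline_dct: float = 6.0        # ΔCt of every target gene at day 0
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if 0 not in self.days:
            raise ConfigurationError("days must include the baseline day 0")
        for line in self.lines:
            if line not in self.line_clusters:
                raise ConfigurationError(f"line {line!r} has no planted cluster")
            if self.line_clusters[line] not in self.planted_log2fc:
                raise ConfigurationError(
                    f"cluster {self.line_clusters[line]!r} has no planted trajectory")


def planted_value(spec: QPCRSpec, line: str, day: int) -> float:
    """Planted log₂FC for (line, day); 0 at the baseline day."""
    if day == 0:
        return 0.0
    traj = spec.planted_log2fc[spec.line_clusters[line]]
    return float(traj[min(day, len(traj)) - 1])


def generate_qpcr(spec: QPCRSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate a long-format Ct table: line, gene, day, replicate, ct."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for line in spec.lines:
        for day in spec.days:
            for rep in range(1, spec.replicates + 1):
                rows.append([line, spec.reference_gene, day, rep, spec.reference_ct])
                for gene in spec.genes:
                    ct = (spec.reference_ct + spec.baseline_dct
                          - planted_value(spec, line, day)
                          + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0))
                    rows.append([line, gene, day, rep, ct])
    return pd.DataFrame(rows, columns=["line", "gene", "day", "replicate", "ct"])
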