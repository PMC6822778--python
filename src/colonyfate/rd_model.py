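"""Activator–inhibitor reaction–diffusion model of BMP signalling on confined colonies.

The model couples a BMP-like activator ``b`` and a diffusible secreted
antagonist ``n`` (Noggin together with Nodal-downstream BMP inhibitors,
treated as one pooled species) on a domain that extends beyond the
cell-covered colony.  Production is restricted to the colony; diffusion,
decay and exchange with the well-mixed medium act everywhere:

    db/dt = D_b ∇²b + mask · rho_b b² / (n (1 + kappa b²))
            − mu_b b − lambda_s S(r, t) b + k_ex (c_dose − b)
    dn/dt = D_n ∇²n + mask · rho_n b² − mu_n n

``S(r, t)`` is an optional Nodal-pathway inhibition field (a Gaussian ring
modelled after the interior SMAD2 ring).  The pSMAD1-like readout is
``b / (1 + lambda_s S)``: BMP activity attenuated by Nodal-driven
antagonism.  Units: lengths in μm, time in h, concentrations in arbitrary
units with ``c_dose`` numerically equal to the ng/ml BMP4 dose.

The inhibitor escapes across the colony edge into the cell-free margin,
which depletes it peripherally and organizes the edge-high pSMAD1
gradient; at high dose on wide domains the same network crosses into a
Turing regime and breaks into periodic foci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .errors import AnalysisError, ConfigurationError, IntegrationError

__all__ = [
    "RDParams",
    "Domain",
    "NodalProfile",
    "SignalingField",
    "DispersionSummary",
    "default_params",
    "default_nodal_profile",
    "build_domain",
    "nodal_profile",
    "simulate",
    "linear_stability",
    "readout_radial",
    "interior_maxima",
    "half_decay_length",
]

# Softening constant added to the inhibitor in the activation term so the
# autocatalysis stays finite when n -> 0 (the classical Gierer-Meinhardt
# form is singular there).
N_SOFT = 1.0


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RDParams:
    """Rate constants of the activator–inhibitor network.

    Attributes
    ----------
    D_b, D_n : float
        Diffusivities of activator and inhibitor (μm²/h).  A Turing
        instability of this network requires ``D_n >> D_b``.
    rho_b : float
        Activator autocatalysis rate (1/h).
    rho_n : float
        Inhibitor production rate (1/h).  Setting it to zero emulates a
        Noggin-knockout colony.
    mu_b, mu_n : float
        First-order decay rates (1/h).
    kappa : float
        Activator saturation constant (1/concentration²).
    k_ex : float
        Exchange rate with the well-mixed medium (1/h); the medium holds
        BMP4 at concentration ``c_dose``.
    c_dose : float
        Bath BMP4 concentration (a.u., numerically the ng/ml dose).
    lambda_s : float
        Coupling strength of the Nodal-pathway inhibition field.
    nodal_on : bool
        When False the Nodal inhibition field is forced to zero.
    """

    D_b: float = 15.0
    D_n: float = 15000.0
    rho_b: float = 4.8
    rho_n: float = 1.2
    mu_b: float = 0.35
    mu_n: float = 1.0
    kappa: float = 0.05
    k_ex: float = 0.12
    c_dose: float = 25.0
    lambda_s: float = 1.0
    nodal_on: bool = False

    def validate(self) -> list[str]:
        """Check invariants; return a list of advisory warnings.

        Raises
        ------
        ConfigurationError
            If any rate, diffusivity or dose is negative.
        """
        for name in ("D_b", "D_n", "rho_b", "rho_n", "mu_b", "mu_n",
                     "kappa", "k_ex", "c_dose", "lambda_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        notes = []
        if self.D_b > 0 and self.D_n / self.D_b <= 1.0:
            notes.append("D_n/D_b <= 1: outside classical Turing regime")
        return notes


def default_params(regime: str = "sb", **overrides) -> RDParams:
    """Named parameter presets.

    ``"sb"``   — Nodal signalling blocked (SB-431542-like): pooled-inhibitor
    network only, producing the gradual edge-to-centre pSMAD1 decline.
    ``"nodal"`` — same rates with the Nodal inhibition field switched on,
    reshaping the gradient (peripheral peak plus central rebound at
    moderate dose, sharper decay at high dose).
    ``"turing"`` — weakly saturated, strongly autocatalytic rates that sit
    inside the Turing band at high dose, producing periodic interior foci
    on millimetre-scale colonies.
    """
    base = RDParams()
    if regime == "sb":
        p = base
    elif regime == "nodal":
        p = replace(base, nodal_on=True)
    elif regime == "turing":
        p = replace(base, rho_b=1.0, rho_n=0.02, mu_b=0.3, mu_n=0.5,
                    kappa=1e-5, k_ex=0.05, D_b=15.0, D_n=6e4,
                    c_dose=200.0, nodal_on=False)
    else:
        raise ConfigurationError(f"unknown parameter regime {regime!r}")
    return replace(p, **overrides) if overrides else p


@dataclass(frozen=True)
class Domain:
    """Computational domain: a colony of radius ``R_colony`` embedded in a
    larger cell-free region out to ``R_domain``.

    ``radial-1D`` assumes axisymmetry (nodes along a radius, symmetry at
    r=0, no-flux at R_domain); ``grid-2D`` embeds the disk in the square
    ``[-R_domain, R_domain]²`` with a no-flux outer boundary.
    """

    kind: str
    R_colony: float
    R_domain: float
    h: float
    r: np.ndarray = field(repr=False)            # per-node radius (μm)
    colony_mask: np.ndarray = field(repr=False)  # float {0,1} per node
    volume: np.ndarray = field(repr=False)       # per-node control volume/area
    shape: tuple = ()                            # grid shape for 2-D reshape

    @property
    def n_nodes(self) -> int:
        return self.r.size


def build_domain(kind: str, R_colony: float, R_domain: float, h: float) -> Domain:
    """Discretize the colony-plus-margin domain.

    Parameters
    ----------
    kind : {"radial-1D", "grid-2D"}
    R_colony, R_domain : float
        Colony and computational radii (μm); ``R_domain >= R_colony``.
    h : float
        Grid spacing (μm); at least 20 nodes must span the colony radius.
    """
    if R_colony <= 0 or h <= 0:
        raise ConfigurationError("R_colony and h must be positive")
    if R_domain < R_colony:
        raise ConfigurationError(
            f"R_domain ({R_domain}) must be >= R_colony ({R_colony})")
    if R_colony / h < 20:
        raise ConfigurationError(
            f"grid too coarse: {R_colony / h:.1f} nodes across colony radius (need >= 20)")

    tol = 1e-9 * R_colony
    if kind == "radial-1D":
        n = int(round(R_domain / h)) + 1
        r = np.arange(n) * h
        mask = (r <= R_colony + tol).astype(float)
        # finite-volume areas of annular control cells (2-D measure / 2π)
        r_lo = np.clip(r - h / 2, 0.0, None)
        r_hi = np.minimum(r + h / 2, R_domain)
        vol = (r_hi**2 - r_lo**2) / 2.0
        return Domain(kind, R_colony, R_domain, h, r, mask, vol, shape=(n,))
    if kind == "grid-2D":
        n = 2 * int(round(R_domain / h)) + 1
        x = (np.arange(n) - (n - 1) / 2) * h
        X, Y = np.meshgrid(x, x, indexing="ij")
        r = np.hypot(X, Y).ravel()
        mask = (r <= R_colony + tol).astype(float)
        vol = np.full(r.size, h * h)
        return Domain(kind, R_colony, R_domain, h, r, mask, vol, shape=(n, n))
    raise ConfigurationError(f"unknown domain kind {kind!r}")


@dataclass(frozen=True)
class NodalProfile:
    """Radial Nodal-pathway inhibition field.

    Parametric form: a Gaussian ring of amplitude ``A`` centred at
    ``r_peak_frac * R_colony`` with width ``w`` (μm), ramped in with time
    constant ``tau_ramp`` (h, 0 = static), zero outside the colony.  A
    tabulated radial profile (``r_samples``/``s_samples``) overrides the
    parametric form (linear interpolation).
    """

    A: float = 1.0
    r_peak_frac: float = 0.8
    w: float = 60.0
    tau_ramp: float = 0.0
    r_samples: np.ndarray | None = None
    s_samples: np.ndarray | None = None

    def validate(self) -> None:
        if self.A < 0:
            raise ConfigurationError("Nodal amplitude A must be >= 0")
        if not (0.0 <= self.r_peak_frac <= 1.0):
            raise ConfigurationError("r_peak_frac must lie in [0, 1]")
        if self.w <= 0:
            raise ConfigurationError("ring width w must be > 0")
        if (self.r_samples is None) != (self.s_samples is None):
            raise ConfigurationError("tabulated profile needs both r_samples and s_samples")


def default_nodal_profile(**overrides) -> NodalProfile:
    """Default Nodal inhibition ring (interior SMAD2-like ring at 0.8·R)."""
    return NodalProfile(**overrides) if overrides else NodalProfile()


def half_decay_length(r_bins: np.ndarray, profile: np.ndarray, R_colony: float) -> float:
    """Distance inward from the colony edge over which the readout falls
    halfway from its edge value to its minimum.

    ``r_bins`` are normalised bin centres (r/R as returned by
    :func:`readout_radial`).  Returns ``R_colony`` when the profile never
    crosses the half level (no appreciable decay).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise AnalysisError("half_decay_length needs at least two radial bins")
    edge = profile[-1]
    level = profile.min() + 0.5 * (edge - profile.min())
    r = np.asarray(r_bins, dtype=float) * R_colony
    # scan inward from the edge for the first crossing below the half level
    for i in range(profile.size - 1, 0, -1):
        if profile[i - 1] < level <= profile[i]:
            frac = (level - profile[i - 1]) / (profile[i] - profile[i - 1])
            r_cross = r[i - 1] + frac * (r[i] - r[i - 1])
            return float(R_colony - r_cross)
    return float(R_colony)


def nodal_profile(spec: NodalProfile, domain: Domain, t: float) -> np.ndarray:
    """Evaluate the inhibition field S(r, t) on the domain's nodes.

    ``ramp(t) = 1 − exp(−t/tau_ramp)`` (≡ 1 for a static profile).  The
    field is zero outside the colony.
    """
    spec.validate()
    r = domain.r
    if spec.r_samples is not None:
        rs = np.asarray(spec.r_samples, dtype=float)
        ss = np.asarray(spec.s_samples, dtype=float)
        if rs.min() > 0 or rs.max() < domain.R_colony:
            raise ConfigurationError(
                "tabulated Nodal profile must cover [0, R_colony]")
        s = np.interp(r, rs, ss)
    else:
        mu = spec.r_peak_frac * domain.R_colony
        s = spec.A * np.exp(-((r - mu) ** 2) / (2.0 * spec.w**2))
    ramp = 1.0 if spec.tau_ramp == 0 else 1.0 - np.exp(-t / spec.tau_ramp)
    return ramp * s * domain.colony_mask


@dataclass(frozen=True)
class SignalingField:
    """Snapshot of the signalling state at time ``t`` (h).

    ``b``/``n`` are activator/inhibitor concentrations per node;
    ``readout`` is the pSMAD1-like activity ``b / (1 + lambda_s S)``.
    """

    t: float
    b: np.ndarray
    n: np.ndarray
    readout: np.ndarray


# --------------------------------------------------------------------------
# discrete Laplacians (conservative, no-flux)
# --------------------------------------------------------------------------


def _laplacian(domain: Domain, colony_only: bool = False) -> sparse.csr_matrix:
    """Conservative (finite-volume) no-flux Laplacian.

    With ``colony_only`` the operator carries flux only across faces whose
    both cells lie inside the colony: transport is confined to the
    cell-covered support (used for the cell-associated activator), while
    the full operator lets the freely secreted inhibitor escape into the
    cell-free margin.
    """
    h = domain.h
    if domain.kind == "radial-1D":
        n = domain.n_nodes
        area = (np.arange(n - 1) + 0.5) * h        # face areas (r at face)
        if colony_only:
            inside = domain.colony_mask > 0
            area = area * (inside[:-1] & inside[1:])
        vol = domain.volume
        i_idx = np.arange(n - 1)
        rows = np.concatenate([i_idx, i_idx + 1, i_idx, i_idx + 1])
        cols = np.concatenate([i_idx + 1, i_idx, i_idx, i_idx + 1])
        flux = area / h
        data = np.concatenate([flux / vol[:-1], flux / vol[1:],
                               -flux / vol[:-1], -flux / vol[1:]])
        return sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    # grid-2D: 5-point stencil assembled face by face
    m = domain.shape[0]
    idx = np.arange(m * m).reshape(m, m)
    inside = (domain.colony_mask > 0).reshape(m, m)
    pairs = []
    for a, b in (((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
                 ((slice(None, -1), slice(None)), (slice(1, None), slice(None)))):
        ia, ib = idx[a].ravel(), idx[b].ravel()
        if colony_only:
            keep = (inside[a].ravel() & inside[b].ravel())
            ia, ib = ia[keep], ib[keep]
        pairs.append((ia, ib))
    ia = np.concatenate([p[0] for p in pairs])
    ib = np.concatenate([p[1] for p in pairs])
    w = 1.0 / (h * h)
    rows = np.concatenate([ia, ib, ia, ib])
    cols = np.concatenate([ib, ia, ia, ib])
    data = np.concatenate([np.full(ia.size, w), np.full(ia.size, w),
                           np.full(ia.size, -w), np.full(ia.size, -w)])
    return sparse.coo_matrix((data, (rows, cols)), shape=(m * m, m * m)).tocsr()


def _auto_dt(params: RDParams, nodal_amp: float, save_every: float) -> float:
    # Bound the explicit-reaction Jacobian along the quasi-steady inhibitor
    # nullcline n = rho_n b^2 / mu_n (the trajectory hugs it after a short
    # transient), maximising |df/db| numerically over a wide range of b.
    b_hi = 1.0 / np.sqrt(params.kappa) * 10.0 if params.kappa > 0 else 1e4
    b = np.geomspace(1e-3, max(b_hi, 10.0 * params.c_dose + 10.0), 400)
    n_qss = params.rho_n * b ** 2 / max(params.mu_n, 1e-12)
    f = params.rho_b * b ** 2 / ((n_qss + N_SOFT) * (1.0 + params.kappa * b ** 2))
    slope = float(np.max(np.abs(np.gradient(f, b))))
    J = params.mu_b + params.mu_n + params.k_ex + params.lambda_s * nodal_amp + slope
    dt = 0.25 / max(J, 1e-12)
    return min(dt, save_every, 0.05)


def simulate(
    params: RDParams,
    domain: Domain,
    nodal: NodalProfile | None = None,
    T: float = 24.0,
    save_every: float = 1.0,
    seed: int = 0,
    dt: float | None = None,
    n_init: float | np.ndarray = 0.2,
    b_init: float | np.ndarray = 0.0,
    ic_noise: float = 0.01,
    kinetics: tuple[Callable, Callable] | None = None,
) -> list[SignalingField]:
    """Integrate the RD system and return saved :class:`SignalingField` s.

    Operator splitting: Crank–Nicolson diffusion (unconditionally stable
    at large ``D_n``), explicit reactions with a step bounded by the
    reaction Jacobian.  The seed only perturbs the initial inhibitor field
    (1% multiplicative uniform noise) — required to break symmetry for
    Turing foci; runs are deterministic given the seed.

    ``kinetics`` optionally replaces the default production terms with a
    pair ``(f(b, n), g(b))`` evaluated pointwise (masked to the colony).
    """
    params.validate()
    if T <= 0:
        raise ConfigurationError("T must be > 0")
    if save_every <= 0 or save_every > T:
        raise ConfigurationError("save_every must lie in (0, T]")

    use_nodal = params.nodal_on and nodal is not None
    nodal_amp = nodal.A if use_nodal else 0.0
    if dt is None:
        dt = _auto_dt(params, nodal_amp, save_every)
    n_sub = max(1, int(np.ceil(save_every / dt)))
    dt = save_every / n_sub
    n_saves = int(round(T / save_every))

    # activator transport stays on the cell-covered colony (receptor-bound
    # ligand travels with/between cells); the secreted inhibitor diffuses
    # over the whole domain and escapes across the colony edge.
    I = sparse.identity(domain.n_nodes, format="csr")
    solvers = {}
    for name, D, colony_only in (("b", params.D_b, True), ("n", params.D_n, False)):
        L = _laplacian(domain, colony_only=colony_only)
        A = (I - 0.5 * dt * D * L).tocsc()
        B = (I + 0.5 * dt * D * L).tocsr()
        solvers[name] = (splu(A), B)

    mask = domain.colony_mask
    rng = np.random.default_rng(seed)
    b = np.broadcast_to(np.asarray(b_init, dtype=float), (domain.n_nodes,)).copy()
    n = np.broadcast_to(np.asarray(n_init, dtype=float), (domain.n_nodes,)).copy()
    n *= 1.0 + ic_noise * rng.uniform(-1.0, 1.0, domain.n_nodes)

    if kinetics is None:
        def f_prod(b, n):
            return params.rho_b * b * b / ((n + N_SOFT) * (1.0 + params.kappa * b * b))

        def g_prod(b):
            return params.rho_n * b * b
    else:
        f_prod, g_prod = kinetics

    if use_nodal:
        S_static = nodal.tau_ramp == 0
        # unramped spatial shape; the scalar ramp is re-applied per step
        S_shape = nodal_profile(
            NodalProfile(nodal.A, nodal.r_peak_frac, nodal.w, 0.0,
                         nodal.r_samples, nodal.s_samples), domain, 0.0)
    else:
        S_shape = np.zeros(domain.n_nodes)
        S_static = True

    def S_at(t):
        if not use_nodal:
            return S_shape
        if S_static:
            return S_shape
        return (1.0 - np.exp(-t / nodal.tau_ramp)) * S_shape

    def snapshot(t):
        S = S_at(t)
        return SignalingField(t=t, b=b.copy(), n=n.copy(),
                              readout=b / (1.0 + params.lambda_s * S))

    saved = [snapshot(0.0)]
    t = 0.0
    lu_b, B_b = solvers["b"]
    lu_n, B_n = solvers["n"]
    for i_save in range(n_saves):
        for _ in range(n_sub):
            S = S_at(t)
            Rb = (mask * f_prod(b, n) - params.mu_b * b
                  - params.lambda_s * S * b + params.k_ex * (params.c_dose - b))
            Rn = mask * g_prod(b) - params.mu_n * n
            b = lu_b.solve(B_b @ b + dt * Rb)
            n = lu_n.solve(B_n @ n + dt * Rn)
            t += dt
            if not (np.all(np.isfinite(b)) and np.all(np.isfinite(n))):
                raise IntegrationError(
                    f"non-finite concentration at t = {t:.4f} h (step size {dt:.4g} h)")
            lim = -1e-6 * max(1.0, params.c_dose)
            if b.min() < lim or n.min() < lim:
                raise IntegrationError(
                    f"negative concentration beyond tolerance at t = {t:.4f} h")
            np.clip(b, 0.0, None, out=b)
            np.clip(n, 0.0, None, out=n)
        saved.append(snapshot(round(t, 9)))
    return saved


# --------------------------------------------------------------------------
# linear stability (Turing) analysis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DispersionSummary:
    """Growth rate of spatial modes around the homogeneous steady state."""

    k: np.ndarray                 # wavenumbers (1/μm)
    growth_rate: np.ndarray       # Re λ(k) (1/h)
    steady_state: tuple           # (b*, n*)
    lambda_max: float | None      # fastest-growing wavelength (μm), None if no band

    @property
    def has_turing_band(self) -> bool:
        return self.lambda_max is not None


def _homogeneous_steady_state(params: RDParams) -> tuple[float, float]:
    def n_of_b(b):
        return params.rho_n * b * b / params.mu_n

    def F(b):
        n = n_of_b(b)
        prod = params.rho_b * b * b / ((n + N_SOFT) * (1.0 + params.kappa * b * b))
        return prod - params.mu_b * b + params.k_ex * (params.c_dose - b)

    if params.mu_n <= 0:
        raise AnalysisError("mu_n must be positive for a steady state")
    b_grid = np.logspace(-6, 4, 2000)
    vals = np.array([F(b) for b in b_grid])
    roots = []
    for i in range(len(b_grid) - 1):
        if vals[i] == 0.0:
            roots.append(b_grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(optimize.brentq(F, b_grid[i], b_grid[i + 1]))
    roots = [b for b in roots if b > 1e-9 and n_of_b(b) > 1e-12]
    if not roots:
        raise AnalysisError("no positive homogeneous steady state found")
    b_star = max(roots)
    return b_star, n_of_b(b_star)


def linear_stability(
    params: RDParams,
    k_max: float | None = None,
    n_k: int = 400,
) -> DispersionSummary:
    """Standard Turing dispersion analysis of the mask-free system.

    Finds the positive homogeneous steady state numerically, computes the
    reaction Jacobian (central differences) and returns ``Re λ(k)`` for the
    linearization ``J − k² diag(D_b, D_n)`` on a wavenumber grid, plus the
    fastest-growing wavelength (``None`` when no mode grows).
    """
    params.validate()
    b0, n0 = _homogeneous_steady_state(params)

    def rhs(b, n):
        prod = params.rho_b * b * b / ((n + N_SOFT) * (1.0 + params.kappa * b * b))
        Fb = prod - params.mu_b * b + params.k_ex * (params.c_dose - b)
        Fn = params.rho_n * b * b - params.mu_n * n
        return np.array([Fb, Fn])

    eps_b = 1e-6 * max(b0, 1.0)
    eps_n = 1e-6 * max(n0, 1.0)
    J = np.column_stack([
        (rhs(b0 + eps_b, n0) - rhs(b0 - eps_b, n0)) / (2 * eps_b),
        (rhs(b0, n0 + eps_n) - rhs(b0, n0 - eps_n)) / (2 * eps_n),
    ])

    if k_max is None:
        k_max = 2.0 * np.pi / 20.0  # resolve wavelengths down to 20 μm
    k = np.linspace(0.0, k_max, n_k)
    D = np.diag([params.D_b, params.D_n])
    growth = np.empty_like(k)
    for i, ki in enumerate(k):
        growth[i] = np.linalg.eigvals(J - ki * ki * D).real.max()

    pos = (k > 0) & (growth > 0)
    lam_max = None
    if np.any(pos):
        k_star = k[np.argmax(np.where(k > 0, growth, -np.inf))]
        lam_max = 2.0 * np.pi / k_star
    return DispersionSummary(k=k, growth_rate=growth,
                             steady_state=(b0, n0), lambda_max=lam_max)


# --------------------------------------------------------------------------
# radial readout summaries
# --------------------------------------------------------------------------


def readout_radial(
    field: SignalingField,
    domain: Domain,
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted mean readout over equal-width annuli of the colony.

    Returns ``(bin_centres, means)`` against normalized radius r/R_colony.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    rnorm = domain.r / domain.R_colony
    inside = domain.colony_mask > 0
    w = domain.volume[inside]
    x = rnorm[inside]
    v = field.readout[inside]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=w * v, minlength=n_bins)
    wts = np.bincount(idx, weights=w, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(wts > 0, sums / np.where(wts > 0, wts, 1.0), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, means


def interior_maxima(
    field: SignalingField,
    domain: Domain,
    min_distance: float = 90.0,
    rel_threshold: float = 1.1,
    edge_exclude: float = 0.1,
) -> np.ndarray:
    """Locate interior readout foci on a 2-D colony.

    A focus is a local maximum of the readout within a square window of
    half-width ``min_distance`` (μm) that exceeds ``rel_threshold`` times
    the median interior readout.  The outer ``edge_exclude`` fraction of
    the radius is ignored so the peripheral ring is not counted.

    Returns an (n, 2) array of (x, y) positions in μm relative to the
    colony centre.
    """
    from scipy import ndimage

    if domain.kind != "grid-2D":
        raise AnalysisError("interior_maxima requires a grid-2D domain")
    m = domain.shape[0]
    ro = field.readout.reshape(m, m)
    r = domain.r.reshape(m, m)
    interior = (domain.colony_mask.reshape(m, m) > 0) & \
        (r < (1.0 - edge_exclude) * domain.R_colony)
    if not interior.any():
        return np.empty((0, 2))
    size = 2 * max(1, int(round(min_distance / domain.h))) + 1
    local_max = (ro == ndimage.maximum_filter(ro, size=size)) & interior
    foci = local_max & (ro > rel_threshold * np.median(ro[interior]))
    i0, i1 = np.nonzero(foci)
    centre = (m - 1) / 2.0
    return np.column_stack([(i0 - centre) * domain.h, (i1 - centre) * domain.h])
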