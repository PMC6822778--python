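# Methods

This note documents the model equations, parameter presets, and the main
design choices of the `colonyfate` package. All lengths are in μm, times
in hours, concentrations in arbitrary units (a.u.).

## Reaction–diffusion model (`rd_model`)

State: activator `b` (BMP-like signalling activity) and a pooled
diffusible inhibitor `n`, on a disk colony of radius `R_colony` embedded
in a larger domain of radius `R_domain`. Kinetics are saturating
Gierer–Meinhardt with a bath-exchange source:

```
∂b/∂t = D_b ∇²b + ρ_b b² / ((n + n₀)(1 + κ b²)) − μ_b b
         + k_ex (c_dose − b) − λ_s S(r, t) b          (inside the colony)
∂n/∂t = D_n ∇²n + ρ_n b² − μ_n n
```

- Production terms act only on the colony support (cells produce ligand
  and inhibitor); decay and bath exchange act everywhere.
- `n₀ = 1` is a softening constant that bounds the autocatalysis when the
  inhibitor is knocked out (`ρ_n = 0`); in wild-type regimes `n ≫ n₀`
  so it is negligible.
- `S(r, t)` is an optional secondary-signal (Nodal-like) field that adds
  first-order activator degradation. The observable readout is further
  attenuated as `readout = b / (1 + λ_s S)`: the secondary signal both
  consumes the activator and desensitizes its read-out.
- **Activator diffusion is restricted to the colony support** (no-flux at
  the colony edge), while the inhibitor diffuses across the whole domain.
  Rationale: receptor- and cell-associated activator stays with the
  cells; if it were allowed to leak into the cell-free margin its maximum
  would sit an interior boundary layer away from the rim, destroying the
  edge-peaked profile at every parameterization we scanned. The freely
  secreted inhibitor escaping over the colony edge is precisely the
  mechanism that de-represses the rim.

Integration is forward-Euler with a 5-point (2-D) or radially symmetric
3-point (1-D) Laplacian. The default time step is chosen automatically
from a numerical bound on the kinetic Jacobian along the inhibitor
quasi-steady nullcline, capped at 0.05 h; blow-up or non-finite values
raise `IntegrationError`.

### Presets (`default_params`)

| preset | intent | key values |
| --- | --- | --- |
| `sb` | graded, edge-peaked patterning (secondary signal absent) | D_b=15, D_n=15000, ρ_b=4.8, ρ_n=1.2, μ_b=0.35, μ_n=1.0, κ=0.05, k_ex=0.12, c_dose=25, λ_s=1.0 |
| `nodal` | same kinetics with the secondary-signal field enabled | as `sb`, `nodal_on=True` |
| `turing` | spot-forming regime for large colonies | ρ_b=1.0, ρ_n=0.02, μ_b=0.3, μ_n=0.5, κ=1e-5, k_ex=0.05, D_n=6e4, c_dose=200 |

Calibration rationale for `sb`: with a pooled inhibitor, total inhibitor
scales roughly quadratically with dose, which suppresses the edge
super-linearly and makes the peripheral response bell-shaped in dose.
Saturating the interior autocatalysis (κ b² ≈ 3–5 at working points)
caps the inhibitor's dose sensitivity, giving a strictly increasing
peripheral dose response while keeping the monotone edge-peaked profile
and the size effect (smaller colonies lose proportionally more inhibitor
over the rim, raising the centre). The resulting gradient is deliberately
shallow (centre/edge ≈ 0.85): the requirement is monotonicity, and a
shallow interior is what lets the secondary-signal ring carve out a
*central* readout peak.

### Secondary-signal field (`NodalProfile`)

A Gaussian ring `S(r) = A exp(−(r − r_p)²/(2w²))` with `r_p = 0.8
R_colony`, `w = 60`, `A = 1`, optionally ramped in time as
`1 − exp(−t/τ)`. A tabulated radial profile can be supplied instead.
With the default field, dose-25 runs develop readout maxima at both the
centre and the edge (absent when the field is off), and dose-50 runs have
a shorter half-decay length than field-off runs.

### Derived quantities

- `linear_stability`: dispersion relation of the homogeneous steady state
  (solved numerically on the colony-interior kinetics); returns the
  fastest-growing wavelength `λ_max` when a finite-k band is unstable.
  The `turing` preset gives λ_max ≈ 275 μm.
- `readout_radial`: area-weighted bin means of the readout over
  equal-width radial bins of the colony.
- `half_decay_length`: distance inward from the colony edge at which the
  radial profile first crosses `min + 0.5 (edge − min)`; `R_colony` if it
  never crosses (no decay).
- `interior_maxima` (grid-2D): local maxima via a maximum filter with a
  90 μm minimum-separation window, thresholded at 1.1× the interior
  median (median-relative, so flat fields yield no foci; results are
  insensitive to the factor over 1.05–1.2), excluding the outer 10% of
  the radius (the peripheral ring is not a focus).

## Fate model (`fate_patterning`)

Cumulative exposure `E(x) = ∫ readout dt` (trapezoidal in time) is the
positional signal. Fates: `E < T_low` → SOX2 (pluripotent-like),
`E ≥ T_switch` → GATA3 when the secondary signal is off, BRA when it is
on (the switch re-routes the high-exposure fate), in between → "none".
Defaults `T_low = 200`, `T_switch = 215` a.u.·h were calibrated once so
that the GATA3-like area fraction of the full simulate→exposure→assign
pipeline is non-decreasing in both dose and time over a 4×4 grid, and
were then frozen. `duration_above` (time over a level) is provided as an
alternative exposure statistic.

## Synthetic data (`synthetic_colonies`)

- `generate_plate`: hard-core (minimum separation 10 μm) uniform cell
  placement in each colony disk at 3500 cells/mm², per-channel intensity
  = gain × radial profile (flat / peripheral-ring / ramp / double-peak or
  a callable) × log-normal noise, optional planted per-cell positive
  fractions and off-colony background cells; returns the cells table plus
  a row-aligned ground-truth sidecar. The default density is chosen so
  the default DBSCAN heuristics (below) are reliable.
- `generate_point_pattern`: uniform-random disk points, jittered
  hexagonal lattices, or interior maxima of a high-dose `turing`
  simulation (grid step `max(5, R/100)`, T = 48 h).
- `generate_qpcr`: long-format Ct tables with planted per-line log₂ fold
  changes (`Strong`/`Intermediate`/`Weak` trajectories), a constant-Ct
  reference gene and Gaussian Ct noise; `planted_value` exposes the
  ground truth.

## Quantification (`colony_quant`)

- `assign_colonies`: per-well DBSCAN; default `eps` = 3× the median
  nearest-neighbour distance, `min_samples = 10`. Effective colony radius
  is the 95th percentile of member radii debiased by √0.95 (the 95th
  percentile of radii of uniform points in a disk of radius R is R√0.95).
- `dbscan_reference`: an independent brute-force construction (connected
  components over core points; border points join the lowest-numbered
  neighbouring cluster; clusters numbered by ascending first-core index)
  used as a test oracle; it reproduces scikit-learn's labels exactly.
- `filter_colonies`: drops colonies outside count bounds (0.5–1.5× the
  plate median by default) or radius tolerance (±30% of nominal) — merged
  or fragmented colonies.
- `radial_profile`: per-colony bin means first, then mean/SD/95% t-CI
  across colonies (colonies, not cells, are the replication unit).
- `hex_map`: pointy-top hexagonal binning of colony-relative coordinates
  with per-hex means and min–max normalization.
- `percent_positive`: fixed, Otsu (on pooled log-intensity; threshold
  returned at the upper edge of the last lower-class bin so that
  `value ≤ threshold` reproduces the optimal split), or 2-component
  Gaussian-mixture posterior. Constant channels fall back to the fixed
  method with a warning.

## Spacing statistics (`peak_stats`)

Foci are detected by Otsu-thresholding pooled log-intensities, rasterizing
the selected cells onto a grid, taking 8-connected components, and
dropping components below `min_area` or touching the outer 5% annulus.
Nearest-neighbour distances are histogrammed on 20 fixed bins spanning
[0, R/2]; summary statistics are the histogram's Shannon entropy (bits)
and the base-2 Jensen–Shannon divergence (JSD, in [0, 1] bit) to a
reference histogram. `mc_test` generates matched-count null patterns
(uniform-random, jittered-hex, or RD maxima), uses JSD(observed vs
pooled-null histogram) as the statistic and the add-one estimator
`p = (1 + #{JSD_null ≥ JSD_obs}) / (n_null + 1)`. Calibration: type-I
error at α = 0.05 is within [0.03, 0.07] over 200 replicates, power
against 5%-jitter hexagonal alternatives at n = 30 exceeds 90%.

Worked JSD example: for P = (½, ½, 0, 0) and Q = (¼, ¼, ¼, ¼),
M = (⅜, ⅜, ⅛, ⅛), KL(P‖M) = log₂(4/3) ≈ 0.415037,
KL(Q‖M) ≈ 0.207519, so JSD = ½(KL(P‖M) + KL(Q‖M)) ≈ **0.311278 bits**.
(Each half-term alone is ≈ 0.2075 — a value sometimes misquoted as the
full divergence.)

## Expression analysis (`expression_analysis`)

ΔCt = Ct_gene − Ct_reference within (line, day, replicate); ΔΔCt = ΔCt −
mean ΔCt of the same (line, gene) at the baseline day; log₂FC = −ΔΔCt.
Plate-wide Ct shifts and reference-gene offsets cancel by construction.
`cluster_responders` runs K-means (k = 3, 50 restarts, fixed seed) on
per-line vectors of post-baseline day-mean log₂FC (unstandardized:
clustering is on response magnitude) and names clusters Strong /
Intermediate / Weak by descending cluster-mean log₂FC, making labels
content-based and invariant to row order.
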