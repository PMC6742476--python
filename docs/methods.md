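# Methods

## Geometry

A cell is modelled as a **spherocylinder**: a cylinder of diameter `w`
capped by two hemispheres, with pole-to-pole length `L ≥ w`.  Then

    S = πwL,        V = (π/4)w²L − (π/12)w³,

and the scale-free prefactor γ = S/V^(2/3) depends only on the aspect ratio
η = L/w:

    γ(η) = ηπ (ηπ/4 − π/12)^(−2/3).

γ is strictly increasing from the sphere value 6^(2/3)π^(1/3) ≈ 4.836, so the
inverse map is computed by Brent root-finding on the bracket [1, 10⁴]
(xtol 10⁻¹²); round-trips are exact to better than 10⁻¹⁰ relative.
**Width always means diameter**; coccoid cells are prolate spheroids with
*semi*-axes `a ≤ c` (shape tables carry full axes 2a, 2c in the same
length/width columns).  The spheroid surface formula has a removable 0/0 at
`c = a`; below relative eccentricity 10⁻⁸ the sphere formula is substituted.

A popular back-of-envelope for η ≈ 4 rods combines S = 2πV^(2/3) with
S ≈ 4πw², giving V ≈ √8·w³ ≈ 2.83 w³.  The exact spherocylinder value at
η = 4 is (11π/12)w³ ≈ 2.88 w³; the package always uses the exact cubic
(`rod_dimensions_from_volume`) and exposes the approximation only as a
comparison helper (`approx_rod_sv_eta4`).  (One sometimes sees "V ≈ 8w³"
quoted; that is dimensionally inconsistent with S ≈ 4πw² and S = 2πV^(2/3),
which force the √8, and is not reproduced here.)

## Scaling statistics

`fit_power_law` fits log S = log γ + β log V by **unweighted OLS in log-log
space** (statsmodels), because the data of interest span ~two decades of
volume with multiplicative scatter.  Weighted alternatives move γ only in
its third digit on such data.  The `fixed` mode pins β = 2/3 — the exponent
forced by any constant-aspect-ratio family — and estimates only log γ (mean
of residuals, with the standard error of that mean).  γ's standard error is
delta-method (γ·se(log γ)).

The nutrient growth law V = V₀e^(ακ) combined with S ≈ 2πV^(2/3) yields the
surface-to-volume prediction S/V ≈ 2π V₀^(−1/3) e^(−ακ/3): slow-growing
cells run at higher S/V.

Aspect-ratio samples are summarised by their natural-scale mean and CV
(SD/mean) plus a log-normal MLE (mean and population SD of log η).  The
intergeneration autocorrelation of per-cycle width uses a pooled-pairs
Pearson estimator per lag (lag 0 ≡ 1): the literature expression it stands
in for is citation-only, and the pooled estimator is the standard choice
when many short lineages are available.

## Single-cell model

State per cell: length `L`, width `w`, division-protein amounts.  Dynamics:

- `dL/dt = kL` — exponential elongation at rate `k` (h⁻¹).
- Two-component protein dynamics: cytoplasmic pool `Pc` and ring-bound pool
  `Pr` with `dPc/dt = −k_b·Pc + k_d·Pr + k_P·L`, `dPr/dt = k_b·Pc − k_d·Pr`.
  Division fires at `Pr = P₀ = ρπw` — the ring completes when its linear
  density ρ is reached around the circumference.  In the
  **simple-accumulation limit** (binding much faster than growth) the
  tracked quantity is `P = Pc + Pr − P*` with `dP/dt = k_P·L` and threshold
  `P = P₀`; this is the default mode and the one used in ensemble runs.
- Width control: surface material made in proportion to volume at rate β
  (`dS/dt = βV`) translates, for a spherocylinder, into
  `dw/dt = w(k − βw/4)·(1 − w/3L)/(1 − w/L)` with stable fixed point
  `w = 4k/β`.

Consequences: each cycle adds `ΔL = ρπw·k/k_P` independent of birth length
(the adder), the homeostatic newborn length equals ΔL, and the newborn
aspect ratio is `ρπk/k_P` — independent of β, which only sets the width.

At division the mother splits into daughters `f` and `1−f` of its length
with `f = 0.5 + δ`, `δ ~ N(0, σ)`, default σ = 0.05, truncated to keep
`f ∈ [0.1, 0.9]` (an ~8σ cut, negligible distortion).  Daughters inherit the
mother's width unchanged (no cap bookkeeping at the septum, consistent with
the S, V conventions above) and the protein resets to the birth condition
(`Pr = 0`, `Pc = P*`; `P*` defaults to 0 and cancels in all observables).
This is the model's only stochasticity: production is deterministic given L.

### Parameter defaults and calibration

| parameter | default | units | meaning |
|---|---|---|---|
| k | 0.75 | h⁻¹ | elongation rate (moderate-nutrient growth) |
| β | 3.701·k + 0.996 | h⁻¹μm⁻¹ | surface-synthesis rate, empirical linear fit of 4k/w vs k |
| ρ | 1 | molecules·μm⁻¹ | ring density (sets the protein scale) |
| k_P | ρπk / 2.83 | molecules·μm⁻¹h⁻¹ | production rate, calibrated (below) |
| k_b, k_d | 100k, k_b/100 | h⁻¹ | ring binding/disassembly (k_b ≫ k_d, k) |
| σ (delta_sigma) | 0.05 | – | division-asymmetry SD |

Only the ratio ρπk/k_P is observable, so ρ is fixed at 1 and k_P derived
from a **newborn aspect-ratio target of 2.83**.  Time-averaging exponential
growth over one cycle multiplies the mean by 1/ln2, so the population-mean
aspect ratio sits at 2.83/ln 2 ≈ 4.08, in the homeostatic band observed for
rod-shaped cells.  This is a calibration to published summary statistics,
not a measured rate.  Rates left at `None` in `ModelParams` re-derive from
`k` whenever `k` changes, which implements the physiological coupling used
in shift protocols: k_P and β track the growth rate, so shifts change k/β
(width) while preserving k/k_P (aspect ratio).

### Numerics

Fixed-step classical RK4; default single-cell step dt = min(10⁻³ h, 0.01/k),
ensemble default 2.5×10⁻³ h.  The threshold crossing is located inside the
step by bisection on the step fraction (each probe is one RK4 step from the
pre-step state), to ~10⁻⁹ h; a step in which a daughter would divide again
raises a step-size error rather than silently skipping an event.  With these
settings the numerically added length matches the closed form to ~10⁻¹⁰
relative and has spread < 10⁻⁶ across random birth lengths.  The width ODE's
(1 − w/L)⁻¹ factor is singular at L = w; L is clamped to ≥ 1.001w inside the
derivative — never active for physical newborns, which satisfy L > w.

The two-component mode converges to the simple mode as k_b grows, but only
first-order: the ring lags the total accumulation by the standing
cytoplasmic pool ~k_P·L/k_b, giving a ~1.5% division-time gap at
k_b = 100k that shrinks ∝ 1/k_b.  With symmetric division and no noise the
cycle converges to period ln2/k geometrically (the newborn-length deviation
halves per generation); it is not exactly periodic after a single
generation.

## Ensemble protocols

The population simulator tracks a **fixed-size ensemble of independent
lineages** (mother-machine semantics): at each division one daughter is
kept — with symmetric fraction noise this is an unbiased random choice —
and the sibling is discarded.  Tracking all descendants would grow
exponentially; lineage sampling differs from whole-population sampling in
its age weighting, but steady-state *newborn* statistics are unaffected in
this noise model.  Lineages are initialised at uniformly random phases of
the analytic cycle and burned in (default 10 generations) before t = 0, so
the recorded pre-shift trace is stationary.

Nutrient shifts change k as a step function at t = 0 (β and k_P follow
instantaneously by default).  Outputs: population-mean length/width/surface/
volume on a sampling grid, newborn aspect ratios binned at 10 min, and the
full per-lineage division log.  Production-scale runs use 10⁵ lineages; the
test profile uses 150–1000 with correspondingly wider tolerances (newborn-η
bin standard errors scale as 1/√count).

Perturbations:

- **FtsZ knockdown** — width dynamics off, w pinned at 1 μm, k_P dropped to
  a fraction (default 40%) at t = 0.  Newborn length rises by exactly the
  inverse fraction (ΔL ∝ 1/k_P); at fraction 0 cells filament until a
  configurable length cap and the trace is flagged.
- **MreB depletion / filamentation** — quasi-static sweeps at constant
  population-mean aspect ratio: for each target width, β = 4k/w sets the
  width fixed point and k_P is co-adjusted to hold newborn η at
  target·ln2 (so the population mean sits at the target).  Default targets:
  η = 2.7 over widths 0.9–1.8 μm (MreB) and η = 11.0 over 0.9–1.4 μm
  (filamentation); the latter target describes antibiotic-filamented cells
  and is an input, not a prediction.  The co-adjustment rule is a
  reconstruction — experiments pin only the endpoint widths and the fitted
  aspect ratio, not the path between them.

## Synthetic data

`make_population_table` draws volumes log-uniformly over two decades
(balanced leverage in log-log space), applies S = γV^β with log-normal
scatter (defaults γ = 6.24, β = 2/3, σ_log = 0.05), redraws the rare rows
falling below the sphere bound, and back-solves exact (L, w) per row.
Conditions partition the volume range; growth rates attach via the inverse
growth law.  `make_newborn_table` ties widths to growth rate through
w = 4κ/β(κ) with 3% log-normal noise and draws aspect ratios log-normal
with condition-independent parameters — μ_log = log(4.14) − σ²/2,
σ_log = 0.14, so the mean is 4.14 and CV ≈ 14%, a calibration to printed
summary statistics rather than a resampling of any raw dataset.  What the
generators deliberately do **not** emulate: segmentation/pixelation error of
particular microscopes, condition-specific sample sizes, or the extra
length-at-fixed-width fluctuations seen in single-cell data (exposed as the
free `width_sigma_log`-style noise knobs, with no claimed magnitude).
Passing tests on these tables therefore demonstrate estimator correctness
and internal consistency, not agreement with any particular experiment.

## Known limitations

- No spatial structure: Z-ring positioning, Min oscillations, and septum
  constriction geometry are out of scope; division is a point event.
- Production is deterministic given L; protein-number noise is absent, so
  all cycle-to-cycle variability stems from division asymmetry.
- The lineage ensemble is not a whole-population census; population-mean
  traces carry mother-machine age weighting.
- Helical/spirochete geometries and arbitrary 3D shapes are not modelled;
  the geometry layer covers spherocylinders, prolate spheroids, spheres.
- Steady-state loci from the perturbation sweeps are quasi-static; transient
  loci during the approach differ and are available from the trace outputs.
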