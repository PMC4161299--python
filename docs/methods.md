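# Methods

This note records the models implemented in `hoptrack`, the conventions
and numerical choices behind them, and what the synthetic-data validation
does and does not establish.

## Coordinates, time and events

Positions are continuous, in micrometres, origin at the lower-left image
corner; frames are 0-based and spaced `frame_interval` seconds
(default 0.033 s ≈ 30 fps).  Time windows are half-open `[t, t+Δt)`.  A
trajectory *emerges* at its first observed frame and *vanishes* at its
last observed frame; its observed lifetime is `(n observed frames) · Δt`.
The alternative convention (vanishing = first missing frame) shifts every
per-molecule delay by one frame; we fix the last-observed-frame
convention because it makes a simulated excursion of duration `t_return`
re-emerge at exactly `t = t_return` after the vanishing, which is where
the estimator finds it.

## Simulator

Molecules arrive on a `W×H` membrane as a spatio-temporal Poisson process
with intensity `association_rate` (molecules/µm²/s).  While bound they
take per-axis Gaussian steps of standard deviation `sqrt(2·D_mem·Δt)`
(giving the 2D mean-square displacement `4·D_mem·t`).  Per frame
transition, in order: move, then dissociate with probability
`1 − exp(−k_off·Δt)`, then bleach with probability `1 − exp(−k_bleach·Δt)`.
A dissociating molecule rebinds with probability `p_reb` after an
excursion of fixed duration `t_return` (default 66 ms = 2 frames),
displaced per axis by `sqrt(2·D_cyto·t_return)` — free diffusion for the
excursion time; a two-step random walk would have the identical law.
Fluorophores also bleach *before* association: association events at time
`T` are thinned by `exp(−k_bleach·T)`, representing depletion of the
labeled cytosolic pool.  This is what makes the observed emergence rate
decay as `ρ₀·e^(−k₀T)` with `k₀ ≈ k_bleach`; bleaching only after binding
would leave the emergence rate flat, contradicting the behaviour the
emergence-rate fit is designed to capture.

The domain is periodic (a torus).  This keeps the membrane spatially
homogeneous — the recruitment model's central assumption — without edge
depletion.  Consistently, the analysis of a periodic geometry uses
minimum-image distances and no boundary correction (`l₀ = 0`, edge factor
1).  Real cell masks instead get the arccos edge factor and a contour
perimeter.  No molecules exist at `t = 0`; the field fills by
association, which is why the first mean-lifetime of the movie is
slightly under-dense (absorbed into the fitted `ρ₀` in practice).

Observation applies the same rule as for real movies: per-frame positions
of all unbleached bound molecules are pooled and linked by the
nearest-neighbour linker, so any one-frame displacement ≥ 0.45 µm —
including every hop return — splits the record into separate
trajectories, and `N₀` exceeds the true molecule count by roughly the
number of hops.

Default parameters are the reference condition used throughout the test
suite: association 1 molecule/µm²/s (0.02–1 explored), `D_mem` 0.01
µm²/s, `k_off` 1/s, `p_reb` 0.03, `D_cyto` 1 µm²/s, `t_return` 66 ms,
`k_bleach` 0.03/s, 10×10 µm, 3000 frames of 33 ms, 12 replicate trials.

## Detection and linking

Candidate spots are pixels whose neighbourhood correlates with a Gaussian
template (σ = 2 px) above a threshold (normalized cross-correlation,
default 0.4); the exact neighbourhood size and threshold are tunables, as
only their qualitative role is established.  Candidates are refined by
least-squares fitting of `I·exp(−((x−x₀)²+(y−y₀)²)/2σ²)+J`; the SNR is
the fitted amplitude over the residual standard deviation in the fit
window (configurable to amplitude over background SD).  Fits with σ
< 0.5 px or SNR < 2 are discarded as noise excursions at detection time;
duplicate fits within 1 px are merged keeping the higher SNR.  The
trajectory-level artifact filter then removes tracks with mean SNR ≤ 5 or
mean σ outside [1, 4] px; it is idempotent.

Linking is greedy nearest-pair-first within `d = 0.45 µm`, ties broken by
ascending distance then spot index, no gap closing (a missed frame is a
vanishing).  At high spot densities the linker occasionally absorbs a
fresh emergence into a dying track (or masks a vanishing); at the
reference density (~32 co-visible spots per 100 µm²) this affects ~1–2%
of events and is part of the observation process being modelled, not an
analysis error.  Hop chains stitch a vanishing to the nearest unclaimed
emergence within 2.0 µm and a frame gap of 0–1 (configurable); chains do
not branch, and the chain lifetime spans first emergence to last
vanishing.

## Kinetics fits

**Survival.** `S(mΔt) = #(lifetime ≥ mΔt)/N₀`, anchored at `S(0)=1`,
fitted with `Σ Aᵢ e^(−kᵢt)` by multi-start nonlinear least squares
(uniform weights; log-spaced rate initializations; amplitudes seeded per
start by non-negative linear least squares).  Amplitudes are free rather
than constrained to sum to 1: on model-generated data they sum to ~1
anyway, while geometrically frame-quantized data (e.g. simulator ground
truth) need the small `e^{kΔt}` amplitude inflation for the rates to come
out unbiased.  Fits where an amplitude collapses below 10⁻³ or two rates
nearly merge are flagged `degenerate` — the expected outcome when `n`
exceeds the number of resolvable states.  Model choice across `n` is
reported as a residual comparison (`compare_exp_models`), not a formal
information criterion.

**Displacements.** One-frame displacement distributions are fitted with
the mixture of localization-broadened Rayleigh components given in the
README; the combined per-component variance is `2(DᵢΔt + ε²)` (diffusion
plus measurement error at both endpoints), so the observable floor on D
is `ε²/Δt`.  Two numerical points matter:

* ε is **not identifiable** from the displacement distribution itself —
  only the combined variances are constrained, and any common shift
  between ε² and the `DᵢΔt` fits equally well.  ε must be supplied
  (measured from the MSD intercept, `localization_error_from_msd`) or
  fixed at 0; co-fitting is available but documented as weakly
  identified.
* The histogram fit (bin 0.001 µm) weights residuals by per-bin Poisson
  uncertainty (chi-square).  With uniform weights the dense small-`r`
  bins dominate and the smallest component collapses to D = 0 on a
  substantial fraction of draws; with Poisson weights the smallest
  coefficient is recovered within a few percent at 5×10⁴ displacements.

**Tail probability.** The fitted mixture gives the closed-form
probability of a one-frame displacement beyond `r₀`,
`Σ aᵢ exp(−r₀²/(4(DᵢΔt+ε²)))`, used both for the lateral-diffusion
correction and as a standalone statistic (e.g. the probability of a step
beyond the 0.45 µm link radius).

**Hopping lifetimes.** Chain lifetimes are fitted with a single
exponential `A·e^(−kt)` on the normalized cumulative survival; at least
two distinct lifetimes are required.

## Rebinding estimator

The per-cell probability is the observed emergence count per vanished
molecule in the analysis window minus the recruitment expectation minus
(consecutive-frame window only) the lateral-diffusion band probability.
Design choices:

* **Recruitment expectation** defaults to the per-vanishing empirical sum
  `(1/N₀) Σ_j ρ̂(T_j)·(in-cell annulus area around j)·Δt`.  The closed
  form `ρ̄·[π(r₂²−r₁²) − (2l₀/3S₀)(r₂³−r₁³)]·Δt` with
  `ρ̄ = ρ₀(1−e^(−2k₀T₀))/(2(1−e^(−k₀T₀)))` is also computed; it assumes
  vanishing times are distributed like `ρ(T)`, but vanishings lag
  emergences by one mean residence time, so it overstates the background
  by `≈ e^{k₀·τ}` (~3% at the reference condition).  Both are returned;
  the empirical sum is the default because it is unbiased under the same
  assumptions.
* **Window structure.** Windows are frame-quantized: window *m* contains
  emergences exactly *m* frames after a vanishing.  The same-frame window
  (m = 0) counts co-visible pairs; m = 1 is the consecutive-frame window
  and receives the diffusion subtraction (requiring a diffusion fit —
  omitting it raises); windows m ≥ 2 need none, since the spot had fully
  disappeared.  The inner radius 0.45 µm is a hard observability limit
  for m ≤ 1 (closer pairs are linked, not split) but not for m ≥ 2;
  `r_min_late` optionally relaxes it there.  The in-vivo default window
  (r ∈ [0.45, 2] µm, t ∈ [0, 133] ms) is configuration, not hard-coded.
* **Simulation recovery protocol** (`simulated_rebinding_trials`): counts
  within 2 µm of the vanished position in the window containing the
  excursion return (`[t_return, t_return+Δt)`), from r = 0 since the
  return window is a "late" window.  With the reference hop-displacement
  law (per-axis σ = 0.363 µm) only ~46% of returns exceed 0.45 µm, so a
  0.45 µm inner radius would structurally halve the recovered value; the
  full-disk late window recovers the configured 0.03 with a small
  (~ −3%) bias from bleach-terminated trajectories that never got the
  chance to hop — a property of the estimator itself, reported, not
  corrected.
* The vanished molecule itself is not excluded from `ρ` (negligible for
  large `N₀`), and each cell contributes one equally weighted scalar to
  the group mean regardless of its molecule count.  Group statistics are
  the mean, a t-based 95% CI, and a two-sided Welch t-test against a
  configurable reference group.
* The in-vitro limit replaces the fitted `ρ` by the constant
  `N₀/(S₀T₀)` and drops the boundary term.

Interpretation: positive = emergence near vanishings exceeds the cell
average (rebinding); ~0 = no excess; negative = locally inhibited
association.

## Cell geometry

Area is the mask pixel count × pixel area.  The perimeter is the length
of the marching-squares contour simplified at 1 px tolerance, which
suppresses the pixelation staircase (≤1% error for rectangles and disks
at fine pixel size; raw contour length runs ~5% high on curved outlines).
Boundary distances come from a Euclidean distance transform shifted by
half a pixel so `z → 0` on the contour.  Masks must be single connected
regions; cells are analyzed one mask at a time.

## Validation scope

The test suite and `scripts/acceptance.py` validate parameter recovery on
synthetic data: the simulator's own ground truth (dissociation rate,
diffusion coefficient, bleach decay, rebinding probability) and
three-component dissociation/diffusion mixtures regenerated from reference
parameter sets at realistic sample sizes (16,088 lifetimes, 50,000
displacements, 12 trials).  Problem sizes were chosen as the smallest
that leave comfortable statistical margin for each tolerance.  The
generator emulates homogeneous association, memoryless kinetics, a fixed
excursion time and a single diffusive state; real membranes add spatial
heterogeneity (e.g. cortical actin density), multi-state kinetics,
variable return times, and detection noise.  Passing therefore
establishes the correctness of the estimator chain and its corrections —
not that any particular biological system has these parameter values.
Known limitations: no 3D cytosolic pool, no molecular crowding or
interactions, no drift correction or astigmatic 3D localization, and the
dissociation fit reports raw (bleaching-inclusive) spot-loss rates, as a
survival curve cannot distinguish the two without an independent bleach
measurement.
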