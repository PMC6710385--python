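# Methods

## The model

`qsdyn` models autoinducer-2 (AI-2) quorum sensing in a batch culture of
*Escherichia coli* with three observables:

* **X(t)** — cell density (OD600), a Gompertz curve
  `X(t) = X0 + C·exp(−exp(−B(t−M)))` with initial density `X0`,
  asymptotic amplitude `C`, rate `B` (1/h) and inflection time `M` (h).
  Growth is treated as an exogenous closed form: it drives the
  signalling kinetics but is never affected by them, and it is never
  numerically integrated.
* **A(t)** — extracellular AI-2 activity (arbitrary
  bioluminescence-derived units):

      dA/dt = μ_A − μ_XA − μ_LA

* **L(t)** — *lsr*-operon expression (β-galactosidase reporter units):

      dL/dt = μ_L + μ_AL − μ_R

with rate terms

      μ_A  = kA · X^n1 / (X^n1 + km1^n1)        production (Hill in density)
      μ_XA = kXA · X^n2 / (X^n2 + km2^n2) · A   basal PTS uptake
      μ_LA = kLA · (X/Xδ) · A · L               LsrACDB transporter uptake
      μ_L  = kL · X^n3 / (X^n3 + km3^n3) · A    PTS-driven expression
      μ_AL = kAL · (X/Xδ) · A · L               feedback expression
      μ_R  = kR · L                             LsrR repression

Assumptions worth stating plainly: all synthesised AI-2 is exported and
all imported AI-2 is phosphorylated (no intracellular pools); LsrK/LsrR
action is lumped into the single first-order repression rate `kR`; `L`
has no carrying capacity, so sustained extracellular AI-2 drives
unbounded expression. Every negative term in dA/dt carries a factor A
and every negative term in dL/dt a factor L or A, so the non-negative
orthant is forward-invariant; simulated values within solver round-off
below zero are clipped, anything worse raises an error.

Units: time in hours; `kLA` and `kAL` are used as 1/(β-gal·h) and
1/(activity·h) respectively so that μ_LA and μ_AL carry the units of
their host equations (the source table's printed unit for `kLA` is
dimensionally inconsistent with its rate expression).

Default initial condition is (A, L) = (0, 0): cultures are inoculated at
low density before any AI-2 has accumulated. Default horizon is
[0, 12] h, which covers the full single-culture episode (inflection at
M ≈ 3.3 h, AI-2 depleted well before 12 h).

## Integration

(A, L) are integrated with LSODA (adaptive-step, stiff-capable) at
rtol 1e-8 / atol 1e-10 for reporting-quality trajectories. Inside
optimizer loops the tolerances are relaxed to 1e-6 / 1e-8: the induced
cost error is ~1e-6 relative — far below the optimizer's resolving
power — and halves the calibration time. The PTS uptake switch
(n2 ≈ 9) makes the late-time dynamics moderately stiff, which is why a
stiff-capable method is the default.

## Calibration

The objective is the sum of squared residuals, each normalised by the
per-variable **data** maximum (SSWR):

    SSWR(θ) = Σ_j Σ_i w_ij ((y_ij − ŷ_ij) / max_i y_ij)²

which makes OD, activity and β-gal units commensurable and leaves each
variable's contribution invariant to unit rescaling. Weights default
to 1 and are only perturbed by the weighted bootstrap.

Fitting is two-stage, exploiting the one-way coupling: the four growth
constants are fitted first against the X series alone (closed-form
evaluation, no ODE solves), then frozen while the kinetic constants are
fitted against the A and L series (X excluded from the cost). Two
kinetic parameters are clamped by default — `n3 = 0.001722` and
`Xδ = 5.7953` — the two the identifiability analysis shows to be
practically non-identifiable (see below).

**Sparse L series.** Expression data typically carry fewer points than
OD and activity data. By default the L series is scored at its own
observation times — the adaptive solver evaluates the model exactly
there, so nothing needs interpolating. The alternative protocol of
linearly interpolating the L *data* onto the denser A grid is available
(`equalize=True`, and `interpolate_to_grid` / `equalize_l_series` as
standalone operations) but is not the default: linear interpolation of
a curved series is biased, and on noiseless synthetic data the bias
measurably displaces the cost minimum away from the generating
parameters (a cost of 0.010 is reachable at a point with kR 39% off
truth, while the truth itself scores 0.029). Scoring at the native
times leaves the noiseless minimum exactly at the truth.

**Optimizer.** Classic rand/1/bin Differential Evolution: mutation
`a + F(b−c)` over distinct members, binomial crossover with one
guaranteed gene, strictly-greedy selection, out-of-bounds genes
reflected into the box. Defaults F = 0.5, CR = 0.9, population
10×dimension, at most 300 generations, stopping when the population
cost spread falls below 1e-8. Runs are bit-reproducible given a seed,
and a warm-start point or full population can be injected — the
profile-likelihood continuation and the bootstrap replicates rely on
this. Cost evaluations whose integration fails score a finite penalty
(1e6) rather than aborting the run. Search boxes default to the
published bootstrap confidence intervals where available, [1e-4, 10]
for Hill exponents and [1e-4, 1e3] for unconstrained scale parameters.
(Note one quirk inherited from the source: the published interval for
`kXA`, 400–500, does not contain the published best fit 343.98, so
recovery runs saturate that bound at a ~16% error.)

## Identifiability

Profile likelihood: one parameter is clamped over a scan — 21 points,
log-spaced over [θ*/5, 5θ*] (linear for near-zero exponents), clipped
to the search box — and all other free parameters are re-optimized at
every point. Re-optimization runs as a continuation: each point's DE
population is a small Gaussian cloud (5% of each bound range) around
the neighbouring point's solution, the walk goes outward from the
optimum in both directions, and a reverse inward sweep keeps the
pointwise best, ironing out isolated re-optimization spikes. A
parameter is labelled identifiable when the profile rises above the
minimum by a threshold Δ on *both* sides within the scan; otherwise it
is flagged flat-left / flat-right / flat. Δ defaults to a pointwise
95% chi-square threshold on the weighted-residual scale,
`best · χ²₀.₉₅(1) / (n−1)`, appropriate when the re-optimizations are
converged tightly. At desk-scale continuation budgets the residual
optimizer scatter (~30% of the minimum) exceeds that statistical
threshold (~15% here), so for qualitative shape classification we pass
an explicit Δ equal to the profile minimum — i.e. "flat" means the
cost fails to double anywhere across a 25-fold parameter range. The
observed separation is wide: identifiable profiles rise 5–80×, flat
ones stay within 2×. When profiling a parameter whose published
interval is narrow (kA: ±28%), the scan range is widened back to
[θ*/5, 5θ*] — the profile asks a physical question, not where a
previous bootstrap happened to land.

Two structural facts shape the results. `n3 ≈ 0.0017` makes
`X^n3 ≈ 1` for any density in the observed range, so the expression
Hill term is ≈ 1/2 regardless of `n3` and `km3` — both are flat (and
any small `n3` fits equally well, which is why it is clamped). `Xδ`
enters the model only through the ratios `kLA/Xδ` and `kAL/Xδ`, so
re-optimizing `kLA` and `kAL` compensates *any* `Xδ` within their
boxes: the profile is flat in both directions, not merely to the right
— a structural (ratio) non-identifiability, resolved by clamping `Xδ`
near the late-exponential density.

## Uncertainty

Weighted bootstrap: each replicate draws i.i.d. Exponential(1) weights
(mean 1, variance 1), one per data point, multiplying that point's
squared normalised residual, and re-runs the kinetic fit warm-started
at the baseline optimum with a reduced budget. Replicate r uses RNG
stream `seed + r`, so the whole result is reproducible from one master
seed. 95% intervals are the 2.5/97.5% quantiles of the replicate
estimates with linear interpolation between order statistics (type-7).
Growth parameters are not re-fitted inside replicates: the growth curve
is orthogonal to the kinetic stage and its published uncertainties are
not propagated — re-fitting it per replicate is a straightforward
extension. Pairwise Pearson correlation of the replicate matrix
summarises parameter dependency.

## Co-culture interference

A wild-type strain shares the medium with a LuxS⁻ knockout that senses
and imports AI-2 but cannot make it. The phenomenological device for
competition is capacity sharing: the wild strain grows to
`C_w = f·C` and the knockout to `C_ko = (1−f)·C` (so `C_w + C_ko = C`
exactly), both Gompertz with the shared `X0`, `B`, `M`. AI-2 production
uses the wild density only; uptake sums both strains' PTS and LsrACDB
terms, the knockout's transporter term multiplying the shared
expression variable L (interpreted as the wild strain's operon state —
the knockout carries no expression variable of its own). A pre-culture
head start of τ hours is encoded as a +τ time shift inside the
knockout's Gompertz argument, with the mixed medium starting AI-2-free.

Two model behaviours worth knowing before reading sweep outputs:

* At a 50/50 split neither strain's density approaches the PTS
  half-saturation `km2 ≈ 5.82` (each saturates near 3.0), so the PTS
  uptake switch never fires, extracellular AI-2 is never depleted, and
  the shared L rises monotonically through the 12 h window toward an
  asymptote near 4240 β-gal units. The peak-L ratio against
  monoculture is therefore horizon-dependent: 2.29 at 12 h, ≈3.0 near
  20 h, →3.9 asymptotically. The package reports the 12 h value.
* For the same reason, at a 50/50 split the pre-culture head start
  barely matters (peak-L fractions of monoculture 2.29 → 1.98 as τ
  goes 0 → 5 h): the knockout's PTS term — the mechanism that would
  scavenge AI-2 — never activates at half capacity. Suppression of
  wild-strain expression by a pre-cultured knockout requires the
  knockout to approach the full stationary density C. Under this
  capacity-sharing encoding no tested τ suppresses peak L below 10% of
  the monoculture peak, and `sweep_preculture` honestly reports that
  no suppressing τ exists.

## Synthetic data

The generator simulates the model from a chosen truth (default: the
published best-fit set), samples X and A every 0.5 h and L every 1.5 h
over [0, 10] h — expression assays are sparser than OD/luminescence
reads in practice — and applies multiplicative Gaussian noise
`value·(1 + CV·z)` clipped at zero, CV 5% by default. Multiplicative
noise matches readouts whose magnitudes span decades. What this does
*not* emulate: digitisation error of plotted data, correlated
within-batch errors, detection floors of the reporter assay, or
biological replicate variation — so recovery results bound what the
method can do on clean data of this design, not what any particular
wet dataset will give.

## Problem sizes and numerical choices

Reported simulations use 1201-point grids over 12 h. Recovery runs use
the full default optimizer budget (population 110, ≤300 generations)
on the 21+7-point noiseless design; under that budget the growth
constants return to within 0.01% and kA/kXA/kR to within ~21/17/3%,
the residual spread reflecting the flat cost valleys described above
(kXA saturates its published-interval bound). Profile scans use 21
points with a continuation budget of population 16 × 25 generations
per point; bootstrap demonstrations use 50 replicates at population 16
× 30 generations, warm-started. Degenerate inputs are handled
explicitly: constant growth data triggers a degenerate-fit warning
(amplitude at its bound or inflection outside the window), all-zero
data for a variable is a normalizer error, and extrapolation requests
in interpolation raise rather than guess.

## Known limitations

* The growth-signalling coupling is one-way; nutrient feedback and
  death phase are out of scope.
* No intracellular AI-2-P / LsrK / LsrR species and no stochastic
  (Gillespie) variant.
* The co-culture model shares a single L between strains and a single
  set of growth constants; strain-specific kinetics are not supported.
* Confidence intervals inherit the optimizer's finite budget: very
  flat directions (km3, kLA·Xδ products) produce intervals that span
  much of the search box, which is a faithful statement of the data's
  information content, not an artifact to be narrowed.
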