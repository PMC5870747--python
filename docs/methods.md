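# Methods

## The statistic

For N scalar observations X_i at locations Z_i with spatial weights w_ij
(non-negative, zero diagonal), Moran's I is

    I = [ Σ_ij w_ij (X_i − X̄)(X_j − X̄) / Σ_ij w_ij ] / [ (1/N) Σ_i (X_i − X̄)² ].

We implement the standard form I = N · Σ_ij w_ij d_i d_j / (S0 · Σ_i d_i²)
with d_i = X_i − X̄ and S0 = Σ_ij w_ij. No row-standardization of weights is
applied: the 1/S0 prefactor already normalises globally, and the strict
10×10 checkerboard then scores exactly −1 under range-1 von Neumann weights
(an N/(N−1) variant would give −100/99). Degenerate inputs (constant field,
S0 = 0, mismatched unit counts) raise typed errors rather than returning
arbitrary numbers.

For circular variates θ_i ∈ (−π, π] (instantaneous oscillator phases),
arithmetic deviations are replaced by signed geodesic displacements from the
circular mean X̄ = atan2(mean sin, mean cos):

    d_i = dθ(θ_i, X̄) = atan2(sin(θ_i − X̄), cos(θ_i − X̄)),

giving the circular index Iθ with the same quadratic form. Phases are
canonically wrapped to (−π, π] on ingestion (−π maps to +π). The circular
mean is undefined when the mean resultant length falls below 1e-9 — e.g.
for balanced anti-phase fields — and the computation then errors rather
than guessing a mean direction; this is an intrinsic limitation of the
circular deviation construction, not of the implementation.

Both statistics are evaluated as a single sparse quadratic form; tests
cross-check them against literal double-loop transcriptions of the defining
formulas (≤ 1e-12 relative error) and against the invariances the formula
implies (affine invariance of I, rotation equivariance of Iθ, invariance
under symmetrization of w).

## Spatial weights

Three constructions cover the use cases:

* **von Neumann lattice neighbourhoods** of range r (binary, Manhattan
  metric, open boundaries). Masked (no-tissue) cells are removed from the
  index space entirely, not zero-weighted, so N counts only valid units.
* **Inverse Euclidean distance** w_ij = ‖Z_i − Z_j‖^(−α) for free
  locations; α sets the interaction range (α = 0 degenerates to uniform
  all-ones weights, asserted in tests). Coincident points are an error.
* **Distance bands** (d_lo, d_hi], half-open to partition distances without
  double counting; these power spatial correlograms (one Moran statistic
  per distance class, with empty bands flagged rather than dropped).

Grid coordinates are 0-based (row, col) with unit cell spacing; weights are
stored as scipy CSR with deterministic (row-major) ordering so Monte-Carlo
runs are bit-reproducible.

## Monte-Carlo inference

The null hypothesis of no spatial autocorrelation is realised two ways:
**resample** (unit values drawn i.i.d. from a stated distribution — fair
binary for scalar fields, uniform on the circle for phases) and
**randomize** (observed values shuffled uniformly over locations,
conditioning on the observed multiset). Both nulls share E[I] = −1/(N−1);
tests verify this against the analytic value and, for N = 4, against
exhaustive enumeration of all 24 permutations. Degenerate draws (constant
fields, undefined circular mean) are rejected and redrawn with a capped
budget; this conditions the null slightly on non-degeneracy, which is the
behaviour one wants when the observed field itself is non-degenerate.

P-values use the add-one rule p = (1 + #{at least as extreme})/(n + 1),
which cannot return 0 from a finite sample; two-sided tests double the
smaller tail, capped at 1. Critical bands are empirical (α/2, 1 − α/2)
quantile pairs with linear interpolation between order statistics. The
10×10 fair-binary benchmark (10⁵ draws) reproduces the reference sampling
distribution: mean ≈ −0.010 (analytic −1/99), s.d. ≈ 0.074. Calibration is
checked by testing 1000 random binary fields against their own resampling
nulls at α = 0.05 (rejection rate ~6%, inside 5% ± 2%).

## Phase extraction

Raw intensity traces are baseline-detrended with a Hodrick–Prescott filter
(statsmodels implementation; the trend minimises squared residuals plus
λ-weighted squared second differences). The default λ = 0.05·(24 h/Δt)⁴ is
the period-scaled convention for circadian data (≈ 2.65·10⁵ at Δt = 0.5 h)
and is always user-overridable; λ → 0 reproduces the data exactly and
linear trends detrend to zero for any λ (both asserted). A literal
quadratic-program solve of the HP objective serves as the test oracle.

Phases and amplitudes come from the analytic signal z(t) = s(t) + iH(s(t))
(scipy's discrete Hilbert transform), θ = atan2(Im z, Re z), A = |z|. The
discrete transform is exact only for infinite records; the first and last
12 h of a record are flagged low-confidence (`edge_mask`), and quantitative
phase-recovery claims in the tests exclude one full oscillation period at
each end, where recovery of planted phases is better than 0.05 rad on
noise-free input. Phase unwrapping is used only for diagnostics (chirp
monotonicity); Iθ and R are wrap-invariant.

Bimodal phase histograms are summarised by a two-component von Mises
mixture fitted by EM: responsibilities in the E-step, weighted circular
means and Bessel-ratio inversion (Best–Fisher start, Newton refinement,
κ capped at 10³) in the M-step; 10 seed-controlled random restarts,
convergence at 1e-8 relative log-likelihood change, up to 2000 iterations.
On effectively unimodal samples EM creeps along the label-degeneracy ridge;
a plateau (< 1e-4 total gain over 50 iterations) is accepted as converged,
and the fit is flagged `effectively_unimodal` when one component absorbs
≥ 95% weight or the mean separation Δμ is smaller than the summed component
spreads (1/√κ₁ + 1/√κ₂). The headline quantity is Δμ = |dθ(μ₁, μ₂)|;
recovery of a planted 1.93 rad separation is within ±0.15 rad on direct
samples and ±0.2 rad through the full movie pipeline across 20 seeds.

## Lattice Kuramoto simulator

N = rows × cols phase oscillators with intrinsic frequencies
ω_i = 2π/τ_i, τ_i ~ Normal(24 h, 2 h) truncated at τ > 1 h (matching the
period dispersal of uncoupled SCN neurons), evolve under

    nearest:     θ̇_i = ω_i + K Σ_{j∈N1(i)} sin(θ_j − θ_i)
    mean-field:  θ̇_i = ω_i + (K/N) Σ_j sin(θ_j − θ_i)

with N1(i) the range-1 von Neumann neighbourhood under open (non-periodic)
boundaries — edge oscillators have 2–3 neighbours, consistent with a finite
tissue and with off-centre spiral defects. The mean-field sum is normalised
by N so K stays intensive across lattice sizes; the nearest-neighbour sum
is left unnormalised. Integration uses LSODA (adaptive, stiff-capable) on
unwrapped phases, rtol 1e-6 / atol 1e-8, wrapping only at output; default
output cadence 0.5 h mirrors experimental sampling. The coupling sum is
expanded as cosθ_i·(A sinθ)_i − sinθ_i·(A cosθ)_i with sparse adjacency A,
so a 25×25 lattice integrates 100 days in under a second.

Simulations reproduce the expected phenomenology: K = 0 matches the
uncoupled closed form; identical oscillators phase-lock (R > 0.99);
steady-state Iθ∞ increases strictly over K ∈ {0, 0.01, 0.1} at a shared
seed; K < 0 drives significant spatial anti-correlation with low R; strong
mean-field coupling gives R∞ > 0.9 with Iθ∞ inside the 95% null band; and
at strong nearest-neighbour coupling some initial conditions form stable
spirals with low R∞ but high Iθ∞. The exact coupling windows in which
spirals appear depend on the particular initial-condition draw, so the
spiral regime is asserted existentially (some seed among those tried)
rather than at a fixed K.

## Synthetic fixtures

The generators emit every input class the methods consume, with ground
truth alongside the data. Binary grids supply the three scalar archetypes
(homogeneous blocks, strict checkerboard, i.i.d. Bernoulli cells); phase
patterns supply spirals, plane waves, uniform-random fields and two von
Mises clusters split across half-planes (defaults: separation 1.93 rad,
κ = 8 — a realistic regional phase gap for long-photoperiod-entrained SCN
tissue). Movies layer per-ROI cosines (24 h period, amplitude 10) over a
baseline offset·e^(−decay·t) + slope·t (offset 100, slope −0.05 h⁻¹ units,
decay 0.01 h⁻¹ — gentle bioluminescence rundown) plus i.i.d. Gaussian
noise, at Δt = 0.5 h for 7 days.

What the fixtures do **not** emulate: photon/camera noise statistics,
spatially correlated noise, amplitude death, cell movement or segmentation
errors, and within-cluster phase gradients (cluster members share one
planted phase exactly). Passing recovery tests therefore demonstrates the
correctness of the numerical pipeline under idealised conditions, not
robustness to every artefact of real recordings. One consequence: a
noise-free one-cluster movie has *identical* phases everywhere, which is a
degenerate input for Iθ (zero circular variance) — the coherent-movie test
asserts R(t) ≈ 1 instead, and Iθ on near-constant fields with i.i.d. noise
sits at the null level by construction, since i.i.d. perturbations carry no
spatial structure.

## Problem sizes and numerical choices

Monte-Carlo nulls default to 10⁴ samples (10⁵ for the sampling-distribution
moments, matching the benchmark to ~0.1% in the mean); all null generation
is vectorised over draws. Lattice benchmarks use 25×25 oscillators for
100 simulated days; the steady-state window discards the first half of the
trajectory and averages the rest, skipping degenerate time points. The ROI
coarse-graining uses trailing crop (top-left divisible region) for frames
not divisible by the ROI edge, and masks ROIs by temporal-mean intensity.
Tables are written with 12 significant digits, which round-trips our
double-precision data losslessly in practice.
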