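# Methods

## The model

The network consists of `N` units, each a group of `D` neurons with
distinct tunings that compete at every discrete timestep (Δt = 1) through a
softmax with gain `g`:

    y_i(t) = Softmax(g · x_i(t)),
    x_id(t) = Σ_{d'} Σ_j J_ij^{dd'} y_jd'(t−1) + u_id(t).

Each unit's activation row lies on the probability simplex; in the
hard-WTA limit `g → ∞` exactly one neuron per unit is active per step
(a "spike"), so the network emits exactly `N` spikes per timestep.  The
quenched weights are i.i.d. Gaussian within each tuning block,

    J_ij^{dd'} ~ Normal(μ_J(d,d') · D/N,  σ_J²(d,d') · D/N),

so the whole connectivity is summarized by two D×D matrices (μ_J, σ_J²).
The 1/N variance scaling keeps single inputs weak while their fluctuations
remain O(1), which is what sustains the fluctuation-driven balanced regime.

## Mean-field rate dynamics

In the hard-WTA limit the population firing rates r_t (a categorical
distribution over tunings) evolve by an argmax-of-Gaussians map:

    r_d(t) = P[X_d > X_{d'} ∀ d'≠d],   X_d ~ Normal(μ_d, σ_d²),
    μ_d  = D Σ_{d'} μ_J(d,d') r_{d'}(t−1) + u_d(t),
    σ_d² = D Σ_{d'} σ_J²(d,d') r_{d'}(t−1) + v_d(t).

For `N → ∞` the map is deterministic.  For finite `N` the step returns the
*realized* rates n/N with n ~ Multinomial(P, N), where P is the map output:
spike counts are what a finite network emits, so the observable rates carry
multinomial noise ~ √(r(1−r)/N) even when P itself is pinned by symmetry.
(Recording P instead would make the unstructured finite-N dynamics exactly
noiseless, because activity conservation fixes every input variance to D
regardless of how the N spikes split across populations.)

### Quadrature

The argmax probability integral is evaluated by Gauss–Hermite quadrature
with M = 201 nodes (configurable), substituting x = μ_d + √2 σ_d z so the
nodes are centered on each integrand's own Gaussian.  The product of
normal CDFs is accumulated as a sum of `log Φ` terms (`scipy.special.
log_ndtr`), which stays accurate for arguments far in the tails, and the
result is renormalized to sum exactly to 1.  Against a 10⁶-sample
Monte-Carlo argmax oracle the quadrature agrees within 3 standard errors
for D ≤ 8 (and at a 9-active fixed point at D = 16, where quiescent
probabilities are ~7·10⁻⁴).  Input variances are floored at
`1e-12 · max(1, max_d σ_d²)` so populations whose variance vanishes (sparse
σ_J² with zero rates) keep a defined integrand; if *all* variances are
zero the map degenerates to an argmax of the means with uniform tie split.

### Linear stability

The Jacobian of the deterministic map is estimated by central finite
differences with step ε = 1e-6 (default), restricted to the simplex
tangent space via an orthonormal basis of the zero-sum subspace; the
reported λ_max is the spectral radius of that (D−1)×(D−1) matrix, the
instability criterion for the discrete map being λ_max > 1.  The
unrestricted D×D Jacobian and its spectrum are reported alongside, since
either convention appears in the literature.  ε = 1e-12 is accepted as an
option but with central differences in double precision it mostly
underflows; steps that produce no change at all trigger a warning and are
escalated ×100 (at most twice).  A Richardson-extrapolated finite
difference serves as the independent oracle in the tests (agreement to
1e-4 relative at D = 3).

### The destabilized attractor and the 10-active branch

With μ_J = 0 and variances concentrated on the diagonal (σ_J = 13), λ_max
at the uniform state crosses 1 between D = 10 (0.951) and D = 11 (1.017):
the uniform distribution destabilizes at D = 11.  The attractor born at
that point has exactly 10 active populations.  `track_destabilized_
attractor` follows this branch: it starts at D* = 11 from the uniform
state plus a tiny seeded zero-sum perturbation, converges, then continues
to larger D by appending a quiescent population and re-converging.  The
branch keeps exactly 10 active populations (threshold 1.5/D) up to D = 16.
Note the multistability of support sizes: from broad random initial
conditions (symmetric Dirichlet(1)) the same network at D = 16 also
reaches stable states with 8 or 9 active populations — the 10-active count
is a property of the branch that emerges from the destabilization, not of
every basin.  Even at D = 11 the outcome is not fully deterministic: the
leading eigenvalue at the uniform state is permutation-degenerate, so the
escape direction is set by the perturbation, and a minority (~10%) of
perturbation seeds land in the coexisting 9-active basin.  The acceptance
computation therefore reports the median count over 10 seeded
perturbations, whose modal and median value is 10.

## Connectivity presets

* `unstructured(D)` — μ_J ≡ 0, σ_J² ≡ 1.
* `multistable(D, mode, diag, offdiag)` — raises the diagonal of μ_J
  (mean mode) or of σ_J (variance mode).  **Scalars in variance mode are
  standard deviations and are stored squared**, matching the (σ_J)₀/(σ_J)₁
  notation of the literature; this is re-stated wherever the scalars
  appear because a silent ×² slip is the easiest bug to make here.
* `sequence(..., shift)` — adds `shift` (mean) or `shift²` (variance) to
  the entries (d+1 mod D, d): population d drives its clockwise neighbor
  d+1 on a ring with θ_d = −π + 2πd/D.  The asymmetric variance term is
  *added* to the baseline off-diagonal variance (variances of independent
  components add), making the preset continuous at shift → 0; whether the
  published networks added or replaced the off-diagonal term is not
  stated, and the additive choice is ours.
* `heterogeneous(D, K_sigma, var_r, seed)` — unit diagonal variances plus
  K_σ seeded off-diagonal entries of value (σ_J²)_r per row.  Here the
  parameter is a variance, following the (σ_J²)_r notation.

## Microscopic simulator

Dense mode stores the flat (N·D)×(N·D) weight matrix (Fortran order, so
the hard-WTA winner-gather reads contiguous columns) and refuses N·D above
a configurable cap (default 20 000 columns).  Blockwise mode stores a
single N×N standard-normal base block Z₀; block (d,d') is reconstructed on
demand as μ·D/N + √(σ²·D/N) · Z₀[rowperm, colperm] with quenched
permutations derived from (seed, d, d').  This preserves the per-block
first and second moments at O(N²) memory (entries within a block are
samples of the same law, merely re-arranged; distinct blocks share values
only up to a random permutation, which leaves all block-level statistics
of the dynamics intact).  The scheme is our own reconstruction of the
published single-block storage idea, whose exact permutation/scaling
details are not in the main text.  Blockwise matvecs are batched into one
Z₀ · V product per step, so sparse-variance networks (heterogeneous
preset) cost O(B·N²) with B the number of nonzero blocks.

Initial conditions (not stated in the source study; our choice): at
g = ∞ each unit's initial winner is uniform over D (seeded); at finite g
rows start at 1/D.  Ties in the hard WTA are broken uniformly from a
dedicated seeded stream — with continuous weights ties have measure zero,
but degenerate fixtures (zero weights, equal inputs) hit them constantly.
External inputs realize per-neuron, per-step independent Gaussians with
the scheduled per-tuning moments (u_d, v_d); epochs are half-open
[t_start, t_end), 0-based, and overlapping epochs add.  All randomness
flows through named streams (weights / init / ties / external /
meanfield) derived from one base seed, so runs are bit-reproducible and
changing one factor does not reshuffle another.

## Analysis conventions

* **ISI CV** uses the population (not sample) standard deviation.
* **ISI CV₂** is the *mean* over consecutive interval pairs of
  2|ISI_{l+1} − ISI_l| / (ISI_{l+1} + ISI_l).  The bare-sum form sometimes
  printed for this statistic cannot equal 1 for a Poisson train (it grows
  with the number of intervals), so the pair-count normalization is used;
  it is exactly 1 in expectation for exponential intervals.  For a
  *discrete-time* Bernoulli train with p = 0.05 the exact expectation is
  0.9524 (enumeration over the geometric ISI law); it approaches 1 only as
  p → 0.  Tests against "CV₂ = 1" at p = 0.05 therefore document the
  continuous-limit idealization, and the measured value for such trains is
  ≈ 0.95.
* Neurons with fewer than 10 ISIs are flagged undersampled and excluded
  from CV/CV₂ summaries (configurable).
* **Active threshold**: a population is active when its window-averaged
  rate exceeds 1.5/D — above the uniform baseline 1/D, below the ≈ 0.1
  rates of active populations in the D = 16 diag-variance regime.  The
  threshold is configurable; note that for 11 ≤ D ≤ 14 the 10-active
  branch sits *below* 1.5/D (10 populations at rate ≈ 0.1 < 1.5/D), so
  counts in that window need either the default threshold at D ≥ 15 or a
  custom one.
* **Autocovariance** is the biased estimator after mean subtraction.
* **Sequence speed**: circular means per step, phase-unwrapped, least-
  squares slope × D/2π; positive = clockwise (d → d+1).
* **Chaos test** follows the six-step perturbation protocol: 10-step
  burn-in, clone, swap the most/least active neuron of one seeded unit,
  co-evolve 20 steps with identical external draws (each clone holds its
  own tie-break stream; ties are measure-zero in the regimes tested),
  record Euclidean distances; chaotic iff the final distance exceeds the
  first post-perturbation distance ("endpoint" criterion; a log-slope
  criterion is exposed as an option).  Identical clones can never be
  labeled chaotic.
* **Critical gain**: bisection on g with majority chaos verdicts over a
  fixed list of seeded network realizations; weights per realization are
  sampled once and reused across gains, so the bisection tracks a single
  quenched ensemble.

## Problem sizes and tolerances used in the tests

Everything the tests assert is recomputed at desk scale, chosen as the
smallest sizes at which each phenomenon is cleanly resolved:

* Full/mean-field consistency: N = 2000, D = 5, T = 250; band
  4·√(r(1−r)/N) at ≥ 95% of steps (pure multinomial sampling logic).
* Time-averaged rates vs 1/D: N = 1000, D ∈ {2, 5, 12}; tolerance 5% of
  1/D.  The limiting factor is a quenched finite-size bias of order
  ~2.5/N in the per-population time-averaged rates (measured by scaling
  N), not temporal sampling noise.
* Chaos: D = 5, N = 1000 for the fixed-gain verdicts; critical-gain
  monotonicity over D ∈ {2, 5, 10} at N = 500, 3 votes, tolerance 0.25.
* Heterogeneous regime: mean-field at the published scale (D = 200,
  K_σ = 10) with 121 quadrature nodes for speed; the full-simulation
  irregularity check is scaled down to D = 60, N = 400, T = 1500, which
  keeps ≥ 20 ISIs per typical neuron.

## What the generated data do and do not show

All inputs are synthetic by construction (the study is a self-contained
dynamical model); the fixtures additionally include hand-enumerable
objects (2-unit networks, 3×4 rasters, Bernoulli trains, rotating bumps)
whose expected statistics are known exactly.  Passing tests demonstrate
internal consistency of simulator, theory and statistics — they do not
certify biological realism: the model has no membrane dynamics, no Dale's
law, no within-population rate heterogeneity in the theory (the full
simulator does show such heterogeneity, one visible source of small
theory-vs-simulation discrepancies), and discrete time.

## Known limitations

* The blockwise permutation scheme is a reconstruction (see above), not a
  transcription of the original appendix.
* The finite-N mean-field noise model captures multinomial count noise
  only, not quenched-weight bias; the full simulator's time-averaged rates
  deviate from 1/D by O(1/N) even for long runs.
* At finite N the hard-WTA dynamics are eventually periodic (finite state
  space); "chaotic" verdicts mean perturbation growth over the test
  horizon, which is the operational sense used throughout.
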