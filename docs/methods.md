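# Methods

## Model

A leaky integrate-and-fire (LIF) readout receives spikes from `N` input
neurons.  Each presynaptic spike at time `t_ij` contributes a
postsynaptic-potential (PSP) kernel `k(t − t_ij)`, so the membrane voltage
is `V(t) = V_rest + Σ_i w_i Σ_j k(t − t_ij)`.  The readout *detects* a
pattern when `V` crosses the threshold θ at least once.  Throughout we use
`V_rest = 0` and `θ = 1`; kernels are causal (`k(t) = 0` for `t < 0`) and
used with their raw amplitudes (no peak normalization — the benchmark
kernel `e^{−t/1.5} − e^{−t}` peaks at ≈ 0.21).

Sampling the kernel-convolved pattern on a grid `t_l = Δ·l` turns it into a
trajectory of feature points `f(t_l) ∈ ℝ^N`; detection is then linear
separation of at least one target point from all background points.  This
geometric identity — hyperplane coefficients are synaptic weights up to the
factor `θ/b` — is what the whole package is built on.

### Kernel families

| family | formula (t ≥ 0) | notes |
|---|---|---|
| `single_exp` | `e^{−t/τ}` | discontinuous onset; piecewise-linear trajectories |
| `alpha` | `(t/τ) e^{−t/τ}` | curved |
| `double_exp` | `e^{−t/τ} − e^{−t/τ_r}` | curved; `τ_r = 0.09 τ` is the EPSP fit ("bio-mimetic") |
| `rc` | charge `1 − e^{−t/τ}` for `t ≤ T_pulse`, then exponential discharge | RC circuit driven by a pulse; continuous at `T_pulse` |
| `triangular` | 0→1 over `[0, τ]`, 1→0 over `[τ, 2τ]` | simplest shape consistent with its intended use |
| `square` | 1 on `[0, τ]` | |

`T_pulse = τ τ_r ln(τ/τ_r)/(τ − τ_r)` is the peak time of the matching
double exponential; the RC kernel defaults to `τ_r = 0.09 τ` so it is the
drop-in substitute for the EPSP-fitted kernel.  The triangular and square
parameterizations are our own choice — only the shapes, not equations, are
conventionally given — and are flagged as such.

### Kink-point sampling

For `rc`, `single_exp`, `triangular` and `square`, every feature component
is of the form `A + B e^{−t/τ}` (or affine) between derivative
discontinuities, so any linear functional of the trajectory is monotone
between "kinks" and attains its extrema exactly at them.  Sampling only the
kink set (for RC: spike times and spike times + `T_pulse`, i.e. `2 N_s`
points for `N_s` spikes, plus a `t = 0` start sample) is therefore lossless
for both training and threshold detection.  A dense grid that misses the
(generally irrational) kink times can only undershoot the true maximum by
one grid step's variation; tests verify a 1-μs grid augmented with the kink
times agrees with the kink maxima to 1e−6 relative.

## Training methods

**Max-margin sweep (`SVMPSPClassifier`).**  All training trajectories are
rescaled per dimension to `[0, 1]` (min/max over the union of all training
points; constant dimensions map to 0 so silent neurons stay inert; the
transform is frozen and reused on test data, which may leave the unit box —
the only leak-free treatment).  Every candidate target point with a nonzero
feature vector is fitted as the single positive against all background
points with liblinear's L2-regularized L1-loss dual solver, cost 10,
stopping tolerance 1e−2, bias enabled; its margin is
`min(D_S⁺, D_S⁻)`, and the best candidate (earliest time on ties) wins.
Two numerical details:

* the dual coordinate-descent shuffling is explicitly seeded — left
  unseeded, liblinear is not run-to-run deterministic;
* an exact pruning rule skips candidates that cannot win: for any
  hyperplane, `min(D_S⁺, D_S⁻) ≤ ½‖p − n‖` for every negative `n`, so
  candidates are swept in decreasing order of `½·min_n‖p − n‖` and the
  sweep stops once this bound falls below the best margin found.  This is
  provably arg-max-preserving and cuts the sweep by an order of magnitude.

The winning hyperplane is composed with the rescaler's affine map and
divided by its bias so the exported weights apply to raw features:
`w = (θ/b′)(W∘s)`, `b′ = b + ⟨W∘s, m⟩`.  This requires `b′ > 0` (silence
below the plane); a non-positive `b′` raises a degenerate-bias error and
the estimator falls back to hyperplane-space decisions.

**Original Tempotron (`TempotronClassifier`).**  From `w = 0`, cycles visit
targets then backgrounds in fixed order; a missed target gets
`w += λ f(t_max)` and a false-positive background `w −= λ f(t_max)` at the
voltage arg-max (`λ = 0.1`).  Training stops at the first update-free
cycle, or after `max_cycles` (10 000 — the rule has no natural cap).  Exact
arg-max ties are broken to the sample with the largest input drive
`‖f‖²` (earliest such sample on a further tie): with zero initial weights
the voltage trace is flat, and the naive earliest-sample tie-break would
update at `f = 0` forever, while an earliest-*nonzero* rule concentrates
all weight on the earliest-firing neurons and inflates the false-positive
rate well above the rule's documented behavior.

**Voltage-margin Tempotron.**  The plain rule first separates at margin
`M_V = 0` (running to convergence under `max_cycles`); then the thresholds
are tightened to `θ + M_V` for targets and `θ − M_V` for backgrounds,
raising `M_V` by 0.01 after every success and continuing from the current
weights.  The search stops once 100 consecutive cycles fail to separate at
the current margin — the patience rule decides whether a *broader* margin
is reachable, not whether the initial problem is solvable.  `M_V = θ` is
the supremum (backgrounds pass through `V = 0`), so the loop is bounded.
The total number of weight vectors evaluated (1 + number of updates) is
reported and used as the evaluation budget for matched GA comparisons.

**Genetic search (`GeneticSVMPSPClassifier`).**  With `n` target patterns a
genotype holds one candidate time index per target; its fitness is the
worst normalized signed margin of a single solver fit with the `n` gene
points as positives: `min(min_genes D_N, −max_negatives D_N)`.  Each
generation of `M = 8`: rank by fitness; the best quarter is mutated (one
uniformly chosen gene shifted by a uniform draw in ±5 candidate steps,
clamped to range), the next quarter recombined pairwise at a uniform split
point (single-gene genotypes are copied unchanged), and the worst half
replaced by fresh uniform genotypes.  The global best is archived outside
the population, so best-so-far fitness is monotone.  The stochastic-search
control uses identical budget accounting with fully random generations.

## Synthetic data

`generate_constant_isi` reproduces the benchmark generator: `N` neurons
fire once each on the arithmetic grid over `[T_min, T_max]` (defaults 10
and 20 ms), assigned by a uniformly random permutation — patterns differ
only in firing order, with a constant pooled ISI of `(T_max−T_min)/(N−1)`.
`generate_uniform` draws one spike per neuron i.i.d. uniform instead.
Noise is truncated Gaussian jitter per spike: out-of-window draws
(window `(0, 30]` ms by default) are redrawn.  What this emulates is a
fixed, noiseless spatiotemporal code perturbed by timing jitter; it does
*not* model rate fluctuations, missing/extra spikes, Poisson background, or
correlated noise, so passing benchmarks bound performance only under pure
timing jitter.

All stochastic components consume one seed through `SeedSequence` spawning:
trial *i* derives independent streams for pattern generation and for each
noise level, so every method within a trial sees byte-identical data and
whole tables reproduce exactly under the same seed.

## Separability scans

For a kernel family and `ν = τ/T`, a scan draws constant-ISI patterns on
`[0, T]` with `T = 10` ms, embeds them with `τ = ν T` on `[0, τ + T]` at
Δ = 0.1 ms, rescales, runs the max-margin sweep (1 target vs. 1 background
by default) and records `D_N` and the synchrony deviation `L_s` — the
maximal per-time standard deviation of the trajectory components, i.e. the
(scaled) distance from the synchrony line `(1, …, 1)`; any global rescaling
of `L_s` moves no peak.  Design choices:

* the default 25-point log-spaced ν grid starts at 0.025 (τ = 0.25 ms) and
  is anchored so the EPSP-matched reference ν = 1.3 is an exact grid point
  (top of grid τ ≈ 66 ms), making peak positions directly comparable to the
  reference value without interpolation;
* each trial reuses the same pattern draw at every ν (common random
  numbers), so the curve over ν is measured on identical task instances —
  the standard variance-reduction design for locating a peak; trials are
  independent (10 per ν by default);
* the `D_N` curve of the EPSP-fitted kernel has a flat top, so its grid
  arg-max wanders one step around ν = 1.3 with trial noise; the `L_s` peak
  is stable at ν = 1.3 and is the recommended way to fix a kernel's time
  constant (`peak_nu(scan, measure="ls")`).  With the cortical EPSP decay
  τ = 23 ms this gives a preferred pattern period of 23/1.3 ≈ 17.7 ms.

## Problem sizes and tests

The test suite runs every benchmark at sizes chosen to make its claim
measurable while keeping the whole suite fast: generalization comparisons
use 20 trials × 50 noisy replicates over σ ∈ {0.5, 1.0, 1.5} ms (the
package's standing benchmark configuration defaults to 100 × 100 over
σ ∈ [0, 2]); the GA-vs-stochastic comparison uses 200 task instances at a
matched budget of 96 evaluations; scans use the full 25-point grid at 10
trials per ν.  The brute-force margin oracle solves, per candidate, the
solver's own hard-margin problem — homogeneous maximum margin in the
bias-augmented space, found as the min-norm point of the signed convex hull
by direct QP — because liblinear's enabled bias is itself regularized and a
bias-ignorant oracle would systematically disagree.  Oracle instances are
drawn in the separable regime the method operates in: with cost `C = 10`,
hinge duality makes the solver prefer sacrificing the single positive point
once the hard margin drops below ≈ `1/√(2C)` ≈ 0.22, so near-degenerate
instances are out of the oracle's (and the method's) scope by construction.

## Known limitations

* One spike per neuron is assumed by the generators and benchmarks; the
  embedding and learners accept multi-spike patterns, but rescaling and
  `D_N` were not re-examined for them.
* The candidate sweep refits one SVM per candidate point; for very long
  windows with curved kernels this is the dominant cost (the pruning rule
  and kink sampling for piecewise-linear kernels are the mitigations).
* The Tempotron's behavior from zero weights depends on how the degenerate
  first arg-max is resolved; our strongest-drive tie-break is one defensible
  choice and is documented above.
* Error bars on scan curves reflect common-random-number trials; absolute
  `sd_DN` values are therefore not comparable to independent-draw designs.
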