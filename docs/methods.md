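# Methods

## Model

The package simulates a two-type contact process for spiking activity in
a neuronal population. The state is the pair of counts (x, y): spiking
neurons recruited from the excited and from the quiescent pool. Four
elementary events move the state:

| event | rate | effect |
| --- | --- | --- |
| recruit excited | μ·N | x → x + 1 |
| recruit quiescent | (1−μ)·N | y → y + 1 |
| remove x-spike | (δx + νΦ)·N | x → x − 1 |
| remove y-spike | (δy + νΦ)·N | y → y − 1 |

with N = x + y, excitation probability μ ∈ [1/2, 1] (excitation
parameter 2μ−1), local inhibition δ > 0 (system size δ⁻¹) and global
inhibition ν ≥ 0. The signed rates sum to the net population drift
`[1 − δN − 2νΦ]·N` on every state with both pools occupied. N = 0 is
absorbing.

### The diversity function Φ

Global inhibition is driven by the composition of the spiking
population through the Simpson concentration index

    Φ(x, y) = (x(x−1) + y(y−1)) / (N(N−1)),   N ≥ 2,

the probability that two spiking neurons drawn without replacement
share an origin. It is 1 for a pure population, (n−1)/(2n−1) → 1/2 on
the balanced diagonal, and 0 at the minimal mixed state (1, 1) — a pure
population drives twice the feedback of a perfectly mixed one. The
index is 0/0 for a single spike; we complete it by the pure-population
limit Φ = 1 at N = 1 and set Φ = 0 at N = 0.

Two boundary choices deserve emphasis, because the qualitative phase
behavior depends on them:

* **Φ(N = 1) = 1.** With global feedback active on a lone spike, a
  single trigger neuron dies at rate ≈ ν and fires an avalanche with
  probability ≈ 1/(1+ν); extinction is reachable at O(1) rate and the
  quiescent regime has short, well-defined lifetimes. Setting Φ(1,0)=0
  instead leaves the δ-channel (rate ~ 10⁻³) as the only exit from
  N = 1, which makes absorption practically unreachable and erases the
  quiescent phase altogether: single-spike populations then simmer at
  N ≈ 10 for thousands of time units at any ν ≤ 1.
* **Deaths remove existing spikes only.** The removal channel of an
  empty pool is switched off (its global-inhibition term has no
  victim), so counts never go negative. The alternative — redirecting
  the empty pool's removal to the other pool, which preserves the net
  drift on pure states — doubles the per-capita death rate of pure
  populations to 2ν and extinguishes the strongly excited sustained
  states (e.g. 2μ−1 = 0.6, ν = 0.6) that the model is meant to
  exhibit. Under the adopted rule a quasi-pure population is sustained
  precisely when μ ≳ ν + δx, which reproduces the sustained/quiescent
  split of the reference parameter points.

### Phase structure

With the composition slaved to its relaxation target x − y = (2μ−1)/δ,
a mixed quasi-equilibrium of the drift exists exactly below the curve
`2μ−1 = (2/3)·sqrt((1−ν)³/(3ν))` — the transcritical bifurcation locus
implemented in `phase.bifurcation_locus` (it degenerates to 2μ−1 = 0 as
ν → 1 and exits the unit parameter square for small ν). The empirical
frontier of the mean-extinction-time surface lies slightly to the right
of the locus at low excitation: stochastic composition oscillations
sustain activity somewhat beyond the deterministic existence boundary.
At excitation 0.1 the measured frontier crossing is ν ≈ 0.74.

## Simulation

`gillespie.simulate` is the textbook direct method in a numba-compiled
loop (10⁷–10⁸ events per second): exponential waiting times from the
total rate, channel selection proportional to rates, ±1 updates. Three
kernels share the stepping logic: full event recording, extinction time
only, and excursion summaries (lifetime, exact activity integral, peak)
— the latter two allocate nothing and make phase maps and avalanche
ensembles cheap. Determinism: per-realization seeds derive from
`SeedSequence([base_seed, index])`; a trajectory whose record buffer
fills is replayed from the same seed into a larger buffer, leaving the
stream unchanged. Ensembles start from a single spike assigned to the
excited pool with probability μ (the same law as the excitation rule;
`uniform` is available), and extinction times are truncated at a cap
(default 10⁴).

Adaptive ensembles grow in batches of 8 until the standard error of the
mean extinction time falls below 5% of its value or 40 realizations are
reached — deep plateau and deep valley cells stop after one batch.

## Avalanche definition

An avalanche is the activity between two quiescent troughs. Two
operations implement this:

* `avalanche.segment` decomposes one uniformly resampled trace into
  trough-to-trough windows around peaks of topographic prominence ≥ 1
  (in count units; plateau peaks at their leftmost sample, trough =
  leftmost minimum between retained peaks, series endpoints as outer
  troughs). Sizes are always the *exact* event-driven integral of N
  over the window, never the grid Riemann sum. The default grid aims at
  ~5 events per bin.
* `avalanche.collect_avalanches` builds ensemble statistics from
  extinction-restart realizations (N(0) = 1, run to extinction or a
  horizon): each realization contributes one record — the
  trough-to-trough window spanning its whole lifetime, whose boundary
  troughs sit at the absorbing state. This is the threshold-free analog
  of "activity between quiescent periods": records are statistically
  independent, sizes are exact integrals, durations are lifetimes.
  Integer count series wiggle by ±1 at every event, so *within* a long
  sustained trace every local maximum carries prominence ≥ 1 and
  fine-grained sub-segmentation floods the ensemble with correlated
  micro-windows; the excursion convention avoids that pathology while
  using the same trough machinery.

## Estimators

* **Log-binned histograms**: geometric bins (default 10 per decade),
  densities per unit of the linear variable, empty bins kept.
* **MLE with KS-selected cutoff**: continuous Pareto likelihood
  `α = 1 + n/Σ ln(s/lo)` with the lower cutoff minimizing the
  Kolmogorov–Smirnov distance over candidate cutoffs (≥ 50 tail
  samples); a truncated-window variant solves the bounded likelihood
  numerically when an upper bound is imposed. On bimodal samples the
  automatic cutoff would lock onto the tail hump, so
  `analyze_avalanches` refits the scaling body below the density valley.
* **Figure-style slopes** (`logbin_ls`): least squares on the log-binned
  density over the widest straight window (RMS residual < 0.12,
  bins with ≥ 5 counts) anchored at the distribution's onset — the
  first well-populated bin at or above the elementary scale S = 1 (one
  spike for one time unit). Anchoring keeps the measured slope on the
  leading scaling regime rather than on whichever shoulder happens to
  be widest in a given realization.
* **Bimodality**: a local density minimum at or above the elementary
  scale followed by a ≥ 1.5×-separated local maximum that exceeds the
  valley level by 2× (an empty valley bin counts as one sample) and
  whose mode bin holds ≥ 10 samples.
* **Duration–size scaling**: mean duration per geometric size bin
  (≥ 3 records per bin); an empty run of at least one decade between
  occupied regions splits the fit into two regimes (`gap_detected`).
* **Regime classification**: supercritical if the size density is
  bimodal; otherwise subcritical if a power law with exponential cutoff
  is AIC-preferred over the pure power law (fitted from the median up)
  *and* the scaling is truncated early — concave log-log density
  (quadratic coefficient < −0.05) or fitted cutoff scale 1/λ below
  twice the system size; critical otherwise. The thresholds
  operationalize "bimodal with a system-size hump", "tapering faster
  than the power law" and "dies within a characteristic scale"; they
  were fixed against synthetic mixtures and truncated samples with
  known structure.

## Deterministic (mean-field style) integration

`meanfield.integrate` solves the drift with adaptive RK45
(rtol 10⁻⁶, atol 10⁻⁹), the real-valued Φ taken as the Simpson branch
for N > 1 and 0 below; nonnegativity is enforced by clipping with a
warning on undershoot below −atol. It is one admissible single-valued
selection of the set-valued dynamics, not "the" unique mean field.
`compare_to_ensemble` averages resampled stochastic trajectories on a
grid against this curve and summarizes both by their global maximum
(peak value/time) and final value; the deterministic run starts from
(x, y) = (1, 1) while the stochastic ensemble starts from a single
spike — both conventions are reported side by side.

## Problem sizes and seeds

Desk-scale defaults, used by the test suite and the acceptance script:
ensembles of ≥ 3,000 avalanches per parameter point (≈ seconds at the
frontier, ≈ 2 minutes in the supercritical regime with a 2,000-unit
observation window per restart), a 21-point ν transect with adaptive
ensembles capped at 40 realizations per cell and extinction cap 10⁴,
and a 10×-system-size robustness run of 1,500 avalanches with a
1,000-unit window. Every stochastic quantity is reproducible from a
single integer seed via `SeedSequence` derivation.

## What the synthetic fixtures do and do not show

The fixture generators (planted step-trajectories with hand-computable
areas, inverse-transform Pareto samples, body-plus-hump mixtures, step
phase surfaces) validate the *machinery*: segmentation recovers planted
bumps exactly, estimators recover known exponents within 2 SE,
bimodality detection has a measured false-positive rate < 5%, frontier
extraction finds a planted cliff. Passing those tests says nothing
about biological realism — the model is a population-level abstraction
with no network topology, no refractoriness and no synaptic dynamics;
its claim is that excitation bias plus two inhibition channels suffice
to organize quiescent, critical-like and epileptiform-like regimes in
one parameter plane.

## Known limitations

* The printed form of Φ's piecewise cases in the source material is
  typographically ambiguous; the completion adopted here (Simpson
  formula for N ≥ 2, pure-population limit at N = 1) was selected
  because it reproduces the reference phase anchors (deep quiescent
  valley, frontier near ν = 0.75 at excitation 0.1, sustained activity
  at strong excitation). Other completions shift the frontier by
  ±0.05–0.1 in ν and can erase the quiescent valley entirely.
* At the nominal frontier point the measured duration exponent
  (≈ 1.4–1.5) is shallower than the idealized critical value 2.0, and
  the supercritical duration slope (≈ −2.2) is shallower than −3: in
  this reconstruction small avalanches grow near-ballistically
  (duration ~ size^0.7–0.9) rather than diffusively (duration ~
  size^1/2), so size and duration exponents are closer to each other
  than the crackling-noise relation α = 1 + (τ−1)/γ with γ = 1/2 would
  give. The duration–size exponent pair (≈ 0.85, ≈ 0.85–0.9) in the
  supercritical two-regime fit brackets the upper idealized value 1.
* Mean extinction times in the plateau are cap-limited by construction;
  the frontier location therefore depends (weakly, through the level
  rule) on the cap.
* The backward-Fokker–Planck expression for the expected extinction
  time and the small-y Taylor frontier approximation are not
  implemented; the frontier is estimated empirically from the
  T-surface.
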