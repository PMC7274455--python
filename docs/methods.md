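# Methods

## Model

The temporal block model treats a longitudinal MEA experiment as one
generative object. Nodes are electrodes; each node of each device draws a
single community label z_u^(d) ~ Categorical(π), π ~ Dirichlet(α·1_k),
fixed for the whole experiment. Time enters only through the community-pair
connection probabilities: η_ij(t) = sigmoid(β_ij + x_ij(t)) with β_ij ~
N(0, 1) and x_ij a draw from a zero-mean Gaussian process. Two squared-
exponential kernels are shared across pairs — κ_in for within-community
pairs (i = j) and κ_out for between-community pairs — so the smoothness of
temporal change is pooled across pairs while each pair keeps its own curve
and offset. Adjacencies are conditionally independent symmetric Bernoulli
draws; the graphs are undirected and hollow, so only unordered node pairs
u < v enter the likelihood.

Assumptions worth keeping in mind: labels do not switch over time (letting
both z and η vary is not identifiable without extra constraints); η is
shared across all devices of a condition, which is what makes communities
comparable across devices; and edges at different DIVs are conditionally
independent given η(t), i.e. all temporal dependence flows through the GP.

The static baseline replaces η_ij(t) by a single η_ij ~ Beta(a, b) shared
across devices and days, with one label vector per device. It is fully
conjugate and serves as the comparison model for held-out prediction.

## Kernel and nugget

κ(t, t') = σ² exp(−(t − t')²/(2ℓ²)), plus a nugget ε added on the diagonal
only. Treating ε as a diagonal nugget (rather than a constant added to
every kernel entry) keeps Gram matrices well conditioned and keeps the
constant component of the latent identified by β; at ε = 0.01 the two
readings differ by at most 0.01 on off-diagonal covariances. ε is fixed
(default 0.01, configurable) rather than inferred.

## Priors and why they look the way they do

* α_i = 1 (flat Dirichlet), β_ij ~ N(0, 1), as the model states.
* σ_in, σ_out ~ half-normal(0.5).
* ℓ_in, ℓ_out ~ Gamma(shape 2) with mean 1.5× the median DIV gap,
  truncated below at half the smallest gap.

The length-scale and scale priors deserve the explanation. The model
contains an exact ridge: adding a constant to x_ij and subtracting it from
β_ij leaves the likelihood unchanged, so the β/latent split is decided by
the priors. A GP with a length scale comparable to the whole DIV span and
a scale near 1 produces near-constant curves of amplitude ~1 — a second,
cheaper home for what β is supposed to encode. Under such permissive
priors the posterior genuinely parks a large share of strong offsets in
the latent mean (e.g. a generative β_12 = −2 recovers as ≈ −1.4 with the
between-pair scale inflated to ≈ 1), because a single between-community
curve carries almost no information about its own kernel. Centering the
length-scale prior near the sampling resolution (median gap between
recordings) and halving the scale prior encodes the intended division of
labor — the GP models day-to-day variation, β models levels — and with it
the validation experiment recovers all three offsets to well within the
posterior spread. The lower truncation at half the smallest gap prevents
degenerate between-recording wiggling. All hyperparameters are exposed on
`PriorSpec`.

## Sampler

The posterior mixes discrete labels with GP quantities, so the kernel is
compound; all moves are exact MCMC updates:

1. **Labels.** Per-node categorical Gibbs with the exact full conditional
   (O(k²T) per node from community-wise edge counts), device by device.
2. **π.** Conjugate Dirichlet.
3. **(β_ij, v_ij).** Elliptical slice sampling on the whitened vector,
   x_ij = L v_ij with L the Cholesky factor of the Gram matrix; after
   whitening the prior is exactly standard normal (the regime where
   elliptical slice sampling needs no tuning), and the non-centered
   parameterization avoids the small-σ funnel.
4. **Ridge shift.** The direction (β += δ, x −= δ) leaves the likelihood
   invariant; with u = L⁻¹1 its prior conditional is Gaussian with
   precision 1 + uᵀu, so δ is Gibbs-sampled exactly. Without this move the
   offset/latent split mixes extremely slowly and posterior means of β
   depend on where the chain entered the ridge.
5. **Kernel hyperparameters.** Random-walk Metropolis on (log σ, log ℓ),
   interweaving the whitened form (v fixed, x recomputed) with the
   centered form (x fixed, v recomputed) — the two forms have
   complementary mixing regimes, and the interweaving brought split R-hat
   on the kernel scales from ≈ 1.5 to ≈ 1.05 on the validation fit. Step
   sizes adapt toward 30% acceptance during warmup only.

Initialization is data-driven: per-device spectral clustering of the
time-averaged adjacency, device labelings aligned by node overlap
(Hungarian assignment), β started at smoothed empirical block logits, and
~20 latent-only updates before the first label sweep. A label sweep
against a prior-drawn η can scramble a good start, and a device whose
labels collapse or swap relative to the others is an absorbing state for
single-node Gibbs moves — single-node updates cannot relabel a whole
device through the intervening low-likelihood states.

Chains: 2 by default; the stated sample count is the post-warmup target
and an equal-length warmup is prepended (the run-half/keep-half
convention). Split R-hat and bulk ESS are computed with arviz on the
continuous scalars; the convergence gate (R-hat < 1.05) warns rather than
hides — summaries are still produced and the flag travels with them.
Determinism: identical (data, k, config, priors, init) give bit-identical
traces; per-chain streams come from spawned seed sequences.

## Label handling

Labels are identified only up to permutation. Reported summaries first
align every chain to the first chain by maximal agreement of
posterior-mode assignments (Hungarian matching), then relabel communities
by decreasing total occupancy — community 1 is always the most populated —
with deterministic tie-breaks (first member node, then label index).
Adjusted mutual information is computed on concatenated per-device
assignments and is label-invariant, so it skips alignment entirely.

## Prediction

For each posterior draw, the latent at new DIVs follows the usual Gaussian
conditional given that draw's training-grid latents and kernel parameters;
a latent sample is pushed through the link and aggregated over draws
(central 94% equal-tailed intervals by default). At ε → 0 this reproduces
the training-point posterior exactly; more than three posterior-mean
length scales beyond the grid the conditional reverts to the GP prior and
a wide-interval warning is raised. Held-out networks are scored by the log
posterior-predictive mass: log-mean-exp over draws of the Bernoulli
likelihood under each draw's labels and predicted η.

## Choosing k

k caps, not sets, the number of communities. Every candidate is fit in
full; the report carries the occupied-community count at the posterior
mode and a DIC (variance-based effective-parameter count, p_D = var(D)/2,
which needs no plug-in over the discrete labels). The chosen k is the
smallest whose occupied count is strictly below k — the cap is then
demonstrably not binding; a fully saturated grid returns the largest k
with a warning.

## Network construction

Channel bursts are maximal merged spans of spikes in which some sliding
100 ms window holds ≥ 4 spikes (burst extent: first to last member spike).
Global bursts group channel-burst starts greedily left-to-right: the
earliest unassigned start anchors a 250 ms window, and ≥ 4 distinct
channels inside it form one global burst; each channel burst joins at most
one. Correlation is zero-lag Pearson on 10 ms-binned counts within each
global-burst window, averaged over the bursts where both channels were
active; silent-in-burst channels get correlation 0 (never NaN) so
downstream graphs are always well formed. Edges require correlation
strictly above the threshold (default 0.20). The anchored reading of the
250 ms criterion, the zero-lag Pearson estimator and the 10 ms bin width
are implementation choices — the qualitative results are designed to be
threshold-robust, and `threshold_sweep` quantifies that.

## Synthetic data

`sample_tsbm` draws panels from the full generative process; the
validation configuration (4 devices × 20 nodes, two fixed communities of
10, DIV grid 11–31 at 3–4 day spacing, σ = 0.25, ℓ = 3, ε = 0.01,
β = (0.5, −2, 0.7)) produces visibly modular graphs and is the test bed
for recovery claims. `simulate_spike_recording` emulates the raw side:
community-synchronized population bursts (≥ 4 jittered spikes per member
channel per event) over low background Poisson firing, with optional
silent channels. What it does not emulate: refractory structure, bursting
rhythms, electrode noise/artifacts, spike-sorting errors, or distance-
dependent correlation — so passing tests certify the pipeline's logic and
the model's recovery on data generated by its own assumptions, not
performance on real recordings.

## Problem sizes used in the checks

The validation fit runs 2 chains × (1000 warmup + 1000 kept) in the
acceptance script and 2 × (500 + 500) in the test suite — both scaled from
the 5000-sample convention, which the fit does not need at this data size.
The temporal-vs-static predictive comparison uses 20 paired replicates at
16 nodes, 2 devices, 6 DIVs with single short chains. Moment checks on the
simulator use 200–400 devices.

## Known limitations

* Binary, undirected edges only; no edge weights or lag/direction
  information survives thresholding.
* One latent curve per community pair: k = 10 means 55 GP curves, and the
  label sweep is O(d·n·k²·T) per iteration — fine at MEA scale (60
  electrodes), not tuned for thousands of nodes.
* σ and ℓ posteriors are weakly informed (a handful of latent values per
  curve) and stay prior-dominated; offsets β and η curves are the
  well-identified quantities, and β means can still shrink by a few tenths
  for strongly negative offsets.
* Missing (device, DIV) cells are simply omitted from the likelihood; the
  GP prior makes this coherent, but heavily missing designs will widen η
  intervals accordingly.
* The static baseline shares one label vector per device across that
  device's DIVs; fitting separate per-DIV models would need external
  community matching across time, which is exactly what the temporal
  model avoids.
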