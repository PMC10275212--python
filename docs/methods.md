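# Methods

This note documents the models, numerical choices and known limitations of
`brainmux`, in the package's own words.

## Connectivity estimation

**Band filtering.** Epochs are filtered in the frequency domain by zeroing
all Fourier coefficients with |f| outside `[f_lo, f_hi)` and inverse
transforming. The half-open convention makes the six canonical bands
(δ 0.5–4, θ 4–8, lower α 8–10, upper α 10–13, β 13–30, γ 30–48 Hz)
partition the spectrum without double counting. A band whose upper edge
reaches the Nyquist frequency is rejected by name.

**Phase lag index.** For a region pair, `PLI = |⟨sign(sin Δφ(t))⟩|`, with
Δφ the instantaneous phase difference of the analytic (Hilbert) signals of
the band-filtered epochs. Phase extraction via the analytic signal is the
standard companion to this coupling measure; the sine formulation maps
phase differences of exactly 0 or π to a contribution of 0 (a literal
reading of the sign of the lag), with a 1e−12 numerical tolerance so that
identical signals score exactly 0. PLI is computed per epoch and averaged
across epochs by default; a pooled variant
(`epoch_average=False`) accumulates the per-sample signs over all epochs
before taking the absolute mean.

*Finite-sample floor.* The epoch-averaged PLI of independent signals does
not converge to 0 as epochs accumulate: each epoch contributes
`|mean of ±1 signs| > 0`, and averaging these magnitudes preserves the
bias. At 3.28-s epochs and physiological detunings the floor is roughly
0.1–0.2. The pooled variant does converge (`∝ 1/√(epochs × samples)`), so
independence checks use it; substantive contrasts (coupled vs uncoupled
pairs) sit well above the floor in either variant.

**BOLD-like layer.** Absolutized Pearson correlation on the concatenated
(non-epoched) series, matching a single continuous acquisition. Negative
correlations are kept by magnitude.

**Structural layer.** Ingested matrices are validated only: symmetry to
1e−9, nonnegativity, zero diagonal (zeroed if within tolerance).

**Region exclusion** removes the same row/column set from every matrix of
every subject and from the atlas mapping, before any network construction.

## MST backbone

Kruskal's algorithm on edge cost `1/w` — equivalently the maximum-weight
spanning tree of `w` (both formulations are cross-checked in the tests,
including against exhaustive Prüfer-sequence enumeration on small graphs).
Zero weights are treated as absent connections, never as infinite-cost
edges; a disconnected positive-weight graph is a hard error reporting the
component count, because the multiplex construction presumes exactly
`N − 1` links per layer. Ties between equal weights are broken by the
sorted `(cost, i, j)` key so output is deterministic; with continuous
weights ties have measure zero.

## Multiplex construction and centrality

Layers are coupled categorically (every pair of layers, node to node) with
interlayer weight ω = 1; frequency bands and modalities have no natural
ordering, so a chain topology is offered only as an option. The leading
eigenpair of the sparse supra-adjacency is computed with a Lanczos solve
(tolerance 1e−10) started from a fixed uniform vector, making runs
bit-reproducible; the eigenvector is oriented so its largest-magnitude
entry is positive, entries below 1e−12 are clamped to zero, and the vector
is renormalized to unit Euclidean norm before aggregation. Aggregation is
the unweighted mean over each node's L entries. For L identical layers the
construction provably reproduces the layer's own EC with eigenvalue
`λ_max(A) + ω(L−1)`, which the tests assert, along with agreement to a
dense eigendecomposition oracle at 1e−9 on every small instance.

Multilayer degree is the overlapping degree (intralayer degrees summed
across layers). Interlayer links are excluded by default: in a multiplex
they add the same constant to every node and carry no between-node
information; an option adds the constant back.

Weighted single-layer EC uses the raw nonnegative weights; inversion
applies only to MST cost.

## Edge significance

For one weighted layer, each null replicate permutes the observed edge
weights uniformly among the observed edge positions — conserving the binary
topology, degree sequence and weight multiset exactly — and then applies
10 strength-matching passes: edges are paired at random and a weight swap
is kept whenever it reduces the squared error between replicate and
original node strengths. The correction is input-adaptive: on matrices
whose strengths carry no structure the passes change almost nothing and
replicates remain plain permutations; on hub-structured heavy-tailed
matrices replicate strengths correlate with the originals at r ≈ 0.87–0.94.
Exact joint preservation of degree, weights and strengths is infeasible in
general, so strength preservation is approximate by design.

Each original edge is tested against its 100 null weights with a two-sided
empirical rank test using the add-one permutation correction:
`p = min(1, 2·min(1 + #{null ≤ obs}, 1 + #{null ≥ obs}) / (n + 1))`,
flagged when `p < α` (α = 0.05). Under exchangeability the expected flagged
fraction is exactly `4/(n+1) = 3.96%` at n = 100, which the calibration
test verifies within 3 standard errors. A literal one-sample
Kolmogorov–Smirnov variant (`method="ks"`, the single observed value
against the null sample) is provided for comparison; the rank test is the
default because a KS test of one observation is statistically degenerate.

*Known limitation.* On heavy-tailed weight multisets at small N
(≲100 regions) the strength-matching step mildly inflates the flagged
fraction on exchangeable inputs (to ~5–6%), because random strength
fluctuations of a few huge weights are chased by the refinement. At the
197-region analysis scale, and for bounded (correlation-like) weights at
any scale, calibration holds.

*Scale dependence of the MST fraction.* The fraction of MST edges flagged
against a weight-shuffle null is necessarily N-dependent: flagging at
α = 0.05 with 100 nulls requires an edge weight near the 98th percentile
of the multiset, while the MST occupies `N−1` of `N(N−1)/2` edges — 3.3%
of edges at N = 60 but 1% at N = 197. High MST fractions (≥ 70%) are
therefore achievable only at the full 197-region scale, which is where the
edge-inference summaries are computed.

## Synthetic cohort

The generator's defaults encode the study conditions: ages uniform on
20–70 years, MEG-like sampling at 1250 Hz with 88 epochs of 4096 samples
(3.28 s), 310 BOLD-like samples, 60 regions by default with a 197-region
preset mirroring the post-exclusion parcel count, and seven equal-as-
possible subnetwork modules including the FPN.

**Latent structure.** Each subject carries a latent integration factor
`g = a0 + a1·age + a2·age² + ε` (defaults `(−2.0, 0.16, −0.0018)`, a
concave trend peaking in mid-life with ~1.1 z-units of systematic range
over the age span, noise sd 0.5). The executive-functioning composite is
`EF = 0.6·z(g) + ε` (noise sd 0.5), and the three component test z-scores
are jittered around EF with their mean constrained to equal it exactly.

**MEG-like layers.** Noisy Kuramoto phase oscillators integrated at the
sampling rate (Euler, phase noise 1.2 rad/√s), one carrier per module
spread over the central 80% of each band plus small per-node jitter
(sd = 6% of bandwidth), so within-module pairs can lock while
between-module pairs beat several times per epoch. Coupling is
leader–follower (directed) with a fixed 0.8-rad lag: a symmetric lagged
coupling is frustrated and settles at zero lag, which the PLI cannot see,
whereas followers of a directed drive settle at the imposed nonzero lag
and give within-module PLI ≈ 0.9. Gains (rad/s, at the 28-region tuning
scale): 12 within modules, 0.1 between modules, and `1.5·exp(0.5·z(g))`
from FPN drivers to non-FPN followers — the planted effect acts through
coupling strength so that it must propagate through PLI estimation, MST
extraction and eigenvector centrality rather than being painted onto the
matrices. The FPN gain is kept in the partial-entrainment regime: if
followers lock fully to the FPN, all non-FPN modules become mutually
coherent through the common drive and the FPN loses its connector
advantage in the backbone (an effect we observed and tuned away from).

**BOLD-like layer.** A module factor model: each region loads 0.6 on its
module factor and 0.25 on a global factor, except FPN regions whose global
loading is `0.35 + 0.25·tanh(z(g))` — integration raises FPN-to-other
correlations monotonically.

**Structural layer.** `w_ij = η_i·η_j·m_ij·ε_ij` with log-normal hub
propensities (σ = 0.6), module factor 3 within modules and
`exp(0.5·z(g))` between FPN and other modules, and log-normal pairwise
noise with σ = 2.0 — weights spanning several orders of magnitude, as
streamline-count matrices do.

**What the generator does not emulate:** source leakage and field spread
(no zero-lag confounds — PLI's robustness to them is untested here),
volume conduction, physiological noise spectra, realistic tractography
biases, and inter-regional heterogeneity of interlayer coupling. Passing
tests therefore demonstrate the correctness and sensitivity of the
analysis chain under its own assumptions, not robustness to those
real-data confounds.

**Problem sizes.** Replicate-cohort recovery runs use 40 subjects,
28 regions and 3 epochs of 256 samples at 256 Hz; the edge-inference
summaries use 5 subjects at 197 regions with 100 null replicates. These
sizes were chosen as the smallest at which the respective effects are
stable, and are stated here so results can be reproduced exactly.

## Statistics

OLS throughout, always with an intercept. Backward elimination starts from
all block-1 predictors plus the forced block-2 predictors and repeatedly
removes the block-1 predictor with the largest partial-F p-value above
0.10 (partial F = squared t in OLS, i.e. drop-one type-III tests);
forward selection adds the eligible predictor with the smallest partial-F
p-value below 0.05. Block-2 predictors are exempt from removal, and by
default are present during block-1 selection (`block2_entry="before"`);
whether the original elimination re-ran after block-2 entry is not
determinable, so the alternative ordering is available as a switch. An
exact fit (zero residual) makes partial p-values 0/0; such undefined
p-values count as 1 for removal decisions, with ties broken toward the
smaller |standardized β|. Standardized β are computed as `b·sd(x)/sd(y)`
(for a single predictor this equals the Pearson correlation, asserted in
tests). Tolerance = 1 − R² of a predictor regressed on the others,
VIF = 1/tolerance, flag threshold 0.2, exact collinearity reported as
tolerance 0 with a singularity flag. The hierarchical age model fits
`y ~ age` then `y ~ age + age²` and reports ΔR² with the F-change test.
The cross-validated R² applies the uncentred percent-scale formula
`100·(1 − Σ(yᵢ−ŷᵢ)²/Σyᵢ²)` to leave-one-out OLS predictions; a singular
leave-one-out design is an error naming the fold. Missing data are
handled by complete-case analysis only.

## Determinism

Every stochastic component consumes an explicit seed (cohorts through
`numpy.random.SeedSequence` spawning; null replicate r uses `seed + r`),
eigen-solves use fixed start vectors, and MST ties are broken
deterministically, so identical configurations reproduce byte-identical
result tables. Disk outputs carry a configuration hash and the layer
order.
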