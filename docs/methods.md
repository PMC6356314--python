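# Methods

This note documents the model choices, parameters, numerical conventions,
and known limitations of the `fdp` pipeline.

## Model overview and assumptions

The pipeline assumes (i) that essential genes are expressed at high levels
within a narrow range and participate in temporally coordinated interactions,
(ii) that a gene's interactions are only meaningful at time points where the
gene is transcriptionally active, and (iii) that conservation across
reference species (ortholog counts) is informative about essentiality. Under
these assumptions the static PPI is sliced into per-time-point active
networks, the slices are fused into one similarity matrix, and genes are
ranked by a conservation-seeded walk plus a local entropy term.

## Stage 1: expression dynamics

**AR order test.** For each admissible order p (1 ≤ p ≤ ⌊(M−1)/2⌋) the series
is lag-embedded into rows m = p+1 … M and the AR(p) model
x_m = β₀ + Σ βᵢ x_{m−i} is fitted by ordinary least squares; it is compared
with the intercept-only model on the same rows via the nested F statistic on
(p, M − 2p − 1) degrees of freedom. This is the simplest exact nested-model
test consistent with scanning p-values over all orders. The minimum p-value
over orders is compared to the 0.01 cutoff *without* multiplicity
correction: a single order that fits well is sufficient evidence of temporal
structure. Empirically (seeded tests), the min-over-17-orders scan labels
about 5% of white-noise profiles time-dependent at M = 36 — inflated above
the nominal 1%, as expected for a maximum over dependent tests, but bounded.

**Degenerate series.** A response with zero variance after lag embedding
returns p-value 1.0 (the order-0 model is exact). Because a constant series
stored in floating point has residuals at rounding scale rather than exactly
zero, the zero-variance guard is relative: RSS₀ ≤ n·(100·eps·(1+|mean|))².
A perfect AR fit (RSS₁ ≤ RSS₀·1e−15) returns 0.0.

**Activity threshold.** Threshold = u + kσ(1−F) with F = 1/(1+σ²), k = 2.5.
σ uses the population formula (divide by M, switchable via
`population_sd=False`): F is a smoothing heuristic, not an inferential
quantity, and the population form keeps the threshold a deterministic
function of the stored series. The activity comparison is strict (>), so a
zero-variance gene — whose threshold equals its constant value — is never
active. The same rule is applied uniformly to time-dependent and
time-independent (non-noise) genes. Genes present in the PPI but absent from
the expression table are never active; missing values are rejected at parse
time rather than imputed.

## Stage 2: network fusion

**Edge weights.** ECC(u,v) = |N(u)∩N(v)| / min(deg u −1, deg v −1); a
degree-1 endpoint (denominator 0) gives ECC = 0, since a leaf can close no
triangle. The weight is exp(ECC/(μ·ε)) with μ = 0.5 and ε the mean of the
two endpoint neighbor-mean ECCs and the edge's own ECC; when ε = 0 the
weight is the neutral 1 (the limit of exp(0/x)).

**Alignment.** Active networks have different node sets, but diffusion needs
conformable matrices. Every matrix is aligned to the union of all active
node sets (genes active at at least one time point). Nodes inactive at a
given time point get all-zero W rows, which become unit-diagonal rows in
both kernels — neutral fixed points of the diffusion.

**Kernels.** The full kernel puts w(u,v)/(2·Σ_{k≠u} w(u,k)) off-diagonal and
½ on the diagonal, so every connected row sums to 1. The KNN kernel keeps
each node's min(K, deg) graph neighbors of largest weight (ties resolved
toward lexicographically smaller gene ids; rows are aligned to sorted ids so
stable index order implements this) and normalizes the kept entries to sum
to ½. K = 20 throughout.

**Diffusion.** Updates are simultaneous (Jacobi-style): both new status
matrices are computed from the previous iteration's pair, matching the
superscripts of the coupled update as written. Exactly 20 iterations are run
per merge; there is no per-iteration renormalization by default (a
`renormalize_diffusion` switch exists for sensitivity analysis). Without
renormalization the matrix scale decays like 4^−t; this is harmless because
every subsequent kernel construction and the final row normalization are
scale-invariant.

**Agglomeration.** The first merge joins the pair of networks closest in
Frobenius distance of their W matrices, ties broken by lowest
(time_index_a, time_index_b); the fused R then plays the role of a weight
matrix (its diagonal is ignored by both kernel constructions, which exclude
self entries) and absorbs the nearest remaining network until one matrix is
left. Time points with no active edges at all are skipped before
agglomeration: an all-zero matrix is at distance zero from any other
all-zero matrix and would distort the merge order while contributing
nothing. The merge sequence is recorded and written as a parenthesized
trace. The fused matrix is not symmetrized; the ranking stage row-normalizes
whatever it receives.

## Stage 3: ranking

The restart vector d normalizes ortholog counts by the network maximum — not
by the sum — so pr is a positive ranking score, not a probability
distribution. Genes missing from the orthology table get count 0 and remain
rankable through topology. The walk pr = (1−a)·d + a·H·pr (a = 0.5) is
iterated from pr⁰ = d to an L1 tolerance of 1e−10 (a defensive cap of 10 000
iterations exists but cannot bind for a < 1; convergence is geometric with
ratio ≤ a). The sum Σ_j h(i,j)·pr(j) is implemented as H·pr — each gene
pulls score from its neighbors — with a `transpose_walk` switch for the
push variant.

IFE uses h(i,k)/|KNN(i,K)| exactly as written, without renormalizing the
terms to sum to 1, and natural logarithms; a gene with a single full-weight
neighbor has IFE 0 and a gene with no neighbors has IFE 0. IFE is min–max
scaled (a constant vector maps to all zeros); pr enters the λ-blend raw.
Ties in FDP break by larger pr, then lexicographic gene id.

## Evaluation

Top-T counts, the jackknife curve (cumulative essentials among the top n),
and the precision–recall curve are consistent transforms of one cumulative
hit vector. By default the recall denominator counts only essentials present
in the ranked (fused-network) gene universe; a flag switches to the full
list.

## Synthetic data generator

The generator emulates the structure the method assumes. The PPI is a
Barabási–Albert preferential-attachment graph (3 edges per node); essential
genes (15% by default) are the earliest — hence hub — nodes. Essential
expression is sinusoidal (period 12 of 36 points, amplitude 1.0, Gaussian
noise sd 0.1) around a high mean (2.5–3.5); half the non-essentials get
lower-mean sinusoids (mean 1–2, noise sd 0.2), 30% get irregular
time-independent profiles (mean 0.8–2, sd 1.0), and the rest get flat
low-mean noise (mean 0.05–0.4, sd 0.05) that exercises the noise filter.
Amplitude matters: a sinusoid of amplitude A has σ ≈ A/√2, and its peak
clears its own k-sigma threshold only for A below roughly 1.6; amplitude 1.0
leaves each periodic gene active around its peak phases. Ortholog counts are
Binomial(99, p) with p uniform on (0.25, 0.75) for essentials and (0, 0.25)
for non-essentials — separated on average, overlapping at the boundary.

Profiles planted as time-independent or noise are redrawn until the
classifier agrees (a handful of redraws at the ~5% null-rejection rate), so
the emitted ground-truth classes are exact rather than merely likely;
periodic profiles are left as drawn and are detected at well above 90%.
Generation is fully reproducible from the seed, byte-identically.

What passing on this fixture does *not* show: real expression compendia have
autocorrelated noise, missing values, amplitude drift across cell cycles,
and PPI false positives/negatives, none of which are modeled; absolute
precision figures on the fixture should not be read as expected performance
on biological data.

## Problem sizes and defaults

Tests and the acceptance script run the full pipeline at n = 300 genes,
M = 36 time points, five seeds — sizes chosen so the planted-recovery
property is measured with reasonable stability while a complete run stays in
the tens of seconds. All defaults (k = 2.5, p-threshold 0.01, noise mean
0.5, μ = 0.5, K = 20, 20 diffusion iterations, a = 0.5, λ = 0.8, ε = 1e−10,
T ∈ {100, 200, 300, 400}) are the method's recommended values and live in
`PipelineConfig`.

## Known limitations

- The fused network is dense (diffusion connects everything), so purely
  local scores on it are weak — consistent with λ = 0 performing poorly; the
  default λ = 0.8 leans on the walk.
- Essential genes that are consistently expressed below the noise cutoff are
  filtered out before ranking and can never be recovered.
- The agglomeration is a greedy chain (R absorbs one network at a time after
  the first pair); no global merge tree is searched.
- Orthology enters only as a count; per-species weighting is out of scope.
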