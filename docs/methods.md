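# Methods

This note records the models, estimators and design choices behind
`cohortnet`, the defaults that matter, and what the synthetic-data tests do
and do not establish about real cohort data.

## Synthetic cohort model

`cohortnet.synthetic` draws cohorts from a latent-Gaussian factor model.
Every variable is a unit-variance Gaussian `x = λ z + s √(1−λ²) ε`
(standardised), where `z` is a shared latent factor — a within-layer *block*
factor or a cross-layer *chain* factor — `λ` its loading, and `s` the
residual noise scale (`noise_sd`, default 1, giving population correlation
`λ_a λ_b` between two variables sharing a factor, i.e. `λ²` for equal
loadings). Discrete variables are deterministic monotone transforms of the
latent value: binary by thresholding at 0, categorical/ordinal by
equiprobable bins at population normal quantiles. Monotone transforms
preserve the dependence, so binned MI detects planted structure across all
value kinds.

Choices worth noting:

- **Chains are a single shared factor.** All members of a planted chain load
  on one latent, so *every* chain pair is dependent (consecutive pairs are
  the nominal "edges"; `GroundTruth.dependent_pairs` lists the rest so
  false-positive tests exclude them). A consequence visible in the examples:
  the direct source→target edge is real and can outscore the full chain
  sequence; chain recovery is therefore asserted as membership in the top-k
  list, not rank 1.
- **Missingness is whole-modality.** Each subject misses an entire layer
  with that layer's probability, independently across subjects and layers
  (missing completely at random). This mirrors how multimodal cohorts
  actually lose data (a subject without a PET scan) and makes the
  pairwise-complete sample size vary across layer pairs, exercising the
  pairwise-complete contract. Pairwise-complete estimation is unbiased under
  MCAR; informative missingness is *not* modelled.
- **Default conditions** (`default_cohort_spec`): 2,000 subjects, group
  fractions 0.4/0.4/0.2 (control/MCI/AD), six layers of ~10 variables with
  imaging layers strongly block-correlated (loading 0.8) and more often
  missing (0.15–0.20), and one genetic → PET → risk → phenotype chain at
  loading 0.7. These are the nominal study conditions for all end-to-end
  experiments; desk-scale runs reduce `n_subjects` to 600–1,000, which keeps
  a loading-0.7 chain (r ≈ 0.49) detectable at α = 0.05 with large margin.

What the generator does **not** emulate: real marginal distributions, site
or batch effects, longitudinal visits, informative missingness, or genuinely
nonlinear (non-monotone) dependence. Passing recovery tests shows the
pipeline's machinery is correct and calibrated under the factor model; it
does not certify performance on any real cohort.

## Association statistics

MI is the plug-in histogram estimate (nats). Continuous variables use
equal-width bins over the observed pairwise-complete range; discrete
variables use their observed levels. The continuous bin count defaults to
`⌈√(n/5)⌉` capped at 10 — with ~2,000 complete pairs that keeps expected
counts per 2-D cell well above 1, bounding the plug-in bias
(≈ (k−1)²/(2N) nats) below the permutation-test resolution. NMI uses the
geometric-mean normalisation `I/√(H_x H_y)` (0 when either entropy is 0),
clipped to [0,1] against estimation jitter.

Permutation p-values use the add-one estimator
`p = (1 + #{null ≥ obs}) / (1 + n_perm)` (finite-sample valid, never 0),
one-tailed for MI — only an excess of dependence is evidence — and
two-tailed on |r| for Pearson, where the sign is meaningful. The null is
generated by permuting one variable over the pairwise-complete rows;
comparisons use a 1e-12 tolerance so exact ties count as exceedances. The
null distribution is computed vectorised (one contingency scatter per batch
of permutations), which is what makes 1,000-permutation tests over all
~1,800 pairs of a 60-variable cohort affordable. Per-pair RNG streams are
derived from a master seed plus the sorted pair name (CRC32), so results are
reproducible and order-independent.

## Network construction

An edge requires permutation significance (p < α, default 0.05) of the pair
statistic — MI for the multilayer network (weight = NMI), Pearson for the
signed network (weight = r). The signed network is built independently over
all variables with its own test, rather than inheriting the MI topology;
this is exposed as the construction function you call, so an MI-topology
variant is a one-line change for a user. Nodes never drop out: isolated
variables stay in both networks (in the dynamics they receive only noise).

Densities treat weights by absolute value (relevant only for the signed
network; NMI weights are non-negative). The average shortest path length
uses distance = 1/weight over ordered pairs; for disconnected graphs the
computation either raises or, on request, restricts to the largest connected
component and says so in the result's meaning.

## Boolean dynamics

States are {0,1}; a node's drive is `S(v) = Σ_u w(u,v)·state(u)` — inactive
neighbours contribute nothing — and the next state is `S(v) > 0`, so exact
ties and isolated nodes go inactive. The within-step order is synchronous
update → noise flip (probability `noise_prob` per non-input node) → clamp of
the input node to the square wave; the order is recorded on the config. The
input node is fully exogenous: exempt from update and noise. Defaults:
100 steps, half-period 10, noise 0.05, initial activation probability 0.5.

A structural consequence of undirected positive coupling: two mutually
positive neighbours sustain each other once active, so without noise much of
a strongly coupled network locks active after the first forcing phase, and
only *pendant* nodes (single edge to the input) track the wave exactly. This
saturation is precisely why simulation noise is on by default — it is the
mechanism that makes cross-correlations informative about coupling strength
— and the test suite asserts both the lock-in and the noise-driven widening
of the cross-correlation distribution.

## Path identification

The cross-correlation of two traces is the Pearson correlation of their
overlapping segments maximised over integer lags in [−max_lag, max_lag],
with max_lag defaulting to the forcing half-period (larger shifts are
aliased by the periodic drive). Zero-variance segments score 0; ties prefer
the smallest |lag|. Edge lengths are 1/cc on the unchanged topology; edges
with cc ≤ `cc_floor` (default 1e-3, which also removes all non-positive
maxima) are dropped as dynamically uninformative — a reciprocal of a
non-positive correlation has no meaning as a distance. One simulation is run
per input node with a seed derived from the master seed; averaging over
repeated stochastic runs is possible by re-running with derived seeds but is
off by default.

k-lowest-score paths use Yen's loopless k-shortest-paths algorithm
(networkx `shortest_simple_paths`, Dijkstra underneath); candidates are
collected until the score strictly exceeds the current k-th best, then
sorted by (score, lexicographic node sequence) so ties are deterministic.
Equivalence with exhaustive simple-path enumeration is asserted on random
graphs of ≤ 8 nodes.

## Permutation negative controls

Null networks preserve the degree sequence exactly: `swaps_per_edge × |E|`
*attempted* double edge swaps (two distinct edges chosen uniformly, one of
the two rewirings chosen uniformly), rejecting any proposal creating a
self-edge or duplicate; the acceptance rate is recorded on the permuted
graph. Weights (with their signs) are then permuted uniformly over the new
edge set, conserving the weight multiset. Each permuted network is
re-simulated and re-analysed with identical configurations, and each
original path is classified by the trichotomy: reappears as a top path /
exists but not top / absent. The specificity flag uses the exists-and-top
fraction (< threshold, default 1%); because mere topological existence is
also informative, the existence fraction and its flag are reported
alongside.

A calibration caveat, measured and documented rather than hidden: the
reappearance probability of a specific multi-edge node sequence in a
degree-permuted sparse network is tiny regardless of whether the original
structure was real, so the control discriminates poorly *against* paths from
unstructured data — under a fully null generator nearly all identified paths
"pass". The control is best read as a robustness check on path identity
(planted structure passes it; it does not by itself bound a false-discovery
rate). The acceptance suite keeps an aspirational ≤ 2% null pass-rate
assertion, which fails for this structural reason.

## Problem sizes

End-to-end experiments run at n = 1,000 subjects, ~60 variables, 200
permutations per pair test, k = 10 paths and 20 permuted control networks;
estimator calibration uses 500 pairs × 200 permutations; path-oracle checks
use 100 random graphs of ≤ 8 nodes. These sizes were chosen so the full
suite completes in minutes while every statistical margin asserted (e.g.
recovery ≥ 80%, type-I error in [0.03, 0.07]) has working room at the
corresponding Monte Carlo resolution.
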