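# Methods

This note documents the models, statistics and design choices behind
`sodanet`, in the spirit of a methods appendix: what is computed, under what
assumptions, with which defaults, and what the synthetic studies do and do
not demonstrate.

## Data model

An `OtuTable` is a samples × OTUs matrix of read counts (or row fractions),
paired with `SampleMetadata` carrying lake, 1-based sampling time index,
season label and a `missing` flag. The default season partition follows a
fourteen-occasion fortnightly design: spring = times 1–4, summer = 5–10,
autumn = 11–14. Dry sampling dates exist only in the metadata
(`missing=True`) and have **no** count row: representing a dry lake as a
zero vector would register as maximal Bray–Curtis dissimilarity and as a
real observation in the association statistics, both artefacts.

Rarefaction draws each sample independently from the multivariate
hypergeometric distribution (subsampling reads without replacement) at a
common depth, by default the minimum row sum. Each sample's draw is seeded
from `(master seed, sample position)`, so results are reproducible and
per-sample draws independent.

The network eligibility filter retains an OTU only if it exceeds 1% relative
abundance in at least one sample (strict) *and* carries more than 10 reads
in at least three samples (strict, on rarefied counts). Both rules are
conjunctive; the filter is idempotent and is the single gatekeeper for the
association stage.

The conductivity→salinity conversion `total ions (g/L) = 0.792·EC (mS/cm) +
179` is a regional calibration for soda lakes; both coefficients are
exposed because the intercept's magnitude is only meaningful within that
calibration's unit convention and should be overridden for other systems.

## Dissimilarity statistics

Bray–Curtis dissimilarity `Σ|u−v| / Σ(u+v)` is the common currency.
*Turnover* is the BC between consecutive *present* samples of one lake;
when a date is missing the pair spans the gap, deliberately, so that
post-refill community replacement appears as a turnover spike. *Distance
decay* groups all within-lake pairwise BC values by time lag.

PERMANOVA follows the distance-based linear-model formulation: squared
distances are Gower-centred (`G = −½ J D² J`), the total sum of squares is
`tr(G)`, and sequential (Type I) term sums of squares are differences of
projection traces `tr((H_k − H_{k−1}) G)` for the growing design matrix
(factor A, then B, then A×B for two-way designs). Pseudo-F uses the
residual mean square; p-values permute samples (rows and columns of the
distance matrix together) with the add-one rule, 999 permutations by
default. One-way results agree exactly with the classical two-group
pseudo-F identity and with an independent one-way implementation; two-way
R² values close to 1 with the residual. Permutation p-values are never 0.

Mantel correlation is the Pearson r of the condensed upper triangles, with
one matrix's ids permuted. The collinearity screen flags variable pairs
with |Pearson r| strictly above 0.7 on pairwise-complete observations,
excluding constants. Group comparisons (e.g. drying vs. non-drying lakes'
turnover) use a two-sided permutation test on the difference of means —
labelled as such in outputs, since a permutation test is the natural
distribution-free choice for such small, unbalanced groups.

## Local similarity analysis

Series are built per lake from the filtered table's relative abundances on
the full sampling grid. Gaps (dry dates) are filled *before* normalization
— linear interpolation for interior gaps and nearest-value for terminal
ones by default (none/zero/nearest also available); the number of
interpolated points is carried into every edge record so downstream users
can discount gap-heavy associations. Series with fewer than six collected
points, or constant series, are excluded. Normalization is the percentileZ
normal-score transform `z_i = Φ⁻¹(rank_i/(n+1))` with averaged ties.

The LS score is computed exactly by a dynamic program over the `2D+1`
alignment diagonals (delay limit `D`, default 1): along each diagonal the
running product sum is clamped at zero (max-subarray-with-reset), once for
positive and once for negative accumulation; the score is the best cell
divided by the full series length `n`. The stored delay is
`d = start_x − start_y` (`d=+1` means x lags y). Ties break toward the
smallest |d|, then positive sign, then the earliest window start, so a
synchronous reading is preferred whenever scores tie. The implementation is
pinned, exactly, to a brute-force enumeration over all window pairs.

Significance is by permutation of one series' time order (add-one rule),
applied to the |LS| magnitude. The matching *global* statistic (SSCC) is
the Spearman rank correlation of the overlap at the LS-optimal delay, with
its own permutation p. Across all pairs of a lake, Benjamini–Hochberg FDR
is applied separately to the LS and SSCC p families; an edge requires
`p < α` **and** `q < α` (α = 0.01) in at least one family. When the global
family passes, the edge is typed SSCC (a global association subsumes a
local one) and weighted by the signed SSCC value; otherwise it is typed LS
and weighted by the signed LS score. Delay-0 edges form the synchronous
network, delay ±1 the time-shifted one.

**Permutation resolution.** With pure permutation p-values, the smallest
attainable p is `1/(n_perm+1)`; for BH q-values to reach `q < α` in a
family of *m* pairs, that floor must lie well below `α·k/m` where *k* is
the number of true discoveries. The pairwise stage therefore defaults to
10 000 permutations (the single-pair helper keeps 1 000). The vectorized
diagonal DP makes this cheap: a 40-series lake (~750 pairs) completes in
well under a minute on one core.

## Synthetic studies

The generator emulates a five-lake, fourteen-occasion fortnightly campaign.
Each OTU follows a latent log-abundance trajectory: baseline (Normal(0,
0.5)) plus a Gaussian seasonal bump (amplitude U(1,2), peak anywhere in the
season, width U(2,4) fortnights) plus Gaussian noise (σ = 0.3). Core OTUs
share their profile across lakes; non-core OTUs are lake-private. Counts
are multinomial draws at fixed depth (default 5000) from the softmax of the
latent matrix; optional Dirichlet overdispersion is available. The
baseline spread and bump shapes were chosen once so that no OTU is so rare
that multinomial rank noise at the default depth destroys any signal it
carries, while keeping a realistic ~30-fold abundance range.

A planted coupling (a, b, sign, delay, ρ) replaces b's anomaly with
`ρ·sign·z_a(t−delay) + √(1−ρ²)·ε'`, where `z_a` is a's standardized latent
and `ε'` a fresh draw of the same observation-noise process N(0, σ²) — ρ
thus weighs the signal against one unit of the generator's noise. This is
imposed on the latent (pre-sampling) series, so downstream recovery
failures are attributable to sampling noise, not generator artefacts.
Lagged couplings read the source on a latent axis extended one step beyond
the observed window, so the boundary point carries genuine lag information
rather than a clamped copy. Coupled targets lose their own bump (their
trajectory *is* the coupling) and receive half their assigned amplitude as
a baseline lift so they are not systematically rarer than bump-carrying
OTUs.

Desiccation removes the listed dates and, from the refill date onward,
mixes a fraction φ of community mass into the lake's private OTUs — a
persistent regime shift, which makes cross-gap Bray–Curtis increase
monotonically with φ.

**What passing on synthetic data does and does not show.** The generator
produces unimodal seasonal dynamics, compositional count noise, missing
dates and planted ground truth — enough to verify that the statistics are
calibrated (type-I error), that planted structure of stated strength is
recovered with correct sign and delay class, and that every pipeline stage
is wired correctly and reproducibly. It does not emulate phylogenetic
correlation among OTUs, taxon-specific sequencing biases, overdispersion
beyond a single Dirichlet parameter, or true ecological interaction
mechanisms; recovery rates measured here do not transfer quantitatively to
field data. Two caveats deserve emphasis: at fourteen time points the
compositional closure alone caps observed rank correlations a few
hundredths below their latent values, and partners coupled to a common
driver are themselves correlated — a "hub" planted with all-synchronous
couplings yields a clique, not a star, and WI (correctly) does not single
out its centre. The hub-recovery experiment therefore spreads partners
across delays so the planted topology is genuinely a star.

## Networks and keystones

Networks are undirected, signed, weighted; only nodes with at least one
significant edge enter, so isolated nodes never dilute density or degree
summaries. Density is `2E/(V(V−1))` (reported 0, flagged, for V ≤ 1).

Weighted topological importance uses absolute weights for strength:
`a_ij = |w_ij| / Σ_k |w_ik|` is the one-step effect of j on i, m-step
effects are matrix powers (walks may revisit nodes), `σ_mj` column-sums
`A^m` with the diagonal excluded at each step, and `WI^n_j` averages
`σ_1..σ_n` (n = 3 by default). This convention — walks, per-step diagonal
exclusion, averaging — is pinned exactly (1e-12) to an independent
walk-enumeration oracle; hand-derivable cases (single edge 2/3; three-leaf
star centre 2, leaf 4/9) follow. One conservation law provides a quick
check: Σ_j σ_1j equals the number of non-isolated nodes. WI is
scale-invariant in the weights. Edge *signs* enter separately: a node's
interaction class is the sign of its summed signed incident weights
(`unspecified` on an exact tie).

Keystones are nodes with WI³ > 1; when fewer than six qualify in a network
the rule expands to WI³ ≥ 1 (the two differ only at exactly 1.0, and both
are implemented literally). Two season-preference rules are exported side
by side, because they answer slightly different questions: the
relative-abundance rule (a season qualifies when its mean exceeds the
study mean by more than the study-period population SD; the largest excess
wins) for network node annotation, and the z-score rule (the single season
with positive mean z; `unspecified` when several) for keystone heatmap
annotation.

## Pipeline and reproducibility

`run_pipeline` drives the full per-lake analysis from one validated config
(YAML/JSON or in-code). All randomness derives from a single master seed
via `numpy.random.SeedSequence` with fixed per-stage keys, so a rerun with
the same config reproduces every output byte; per-lake network stages fail
independently, with failures recorded in the manifest. Default analysis
settings: delay limit 1, α = 0.01, BH q-values, 10 000 LSA permutations,
999 PERMANOVA permutations, WI at three steps, linear gap fill.

Problem sizes used by the test-suite simulations and the acceptance script
— 20 seeds × 40 OTUs × 14 time points for edge recovery, 2 000 white-noise
pairs for calibration, 200 random graphs for the WI oracle, two-lake
studies for end-to-end determinism — are the package's chosen verification
sizes: large enough for the binomial tolerance bands used, small enough to
run routinely on one core.

## Known limitations

- Permutation p-values only; the asymptotic LS p-value approximation is
  not implemented, so very small p's cost permutations.
- SSCC significance is evaluated at the LS-optimal delay (configurable),
  not at delay 0 only.
- The two-way PERMANOVA uses sequential SS in the order given; it is not an
  implementation of marginal (Type II/III) tests.
- The keystone expansion rule's `>1` vs `≥1` distinction only matters for
  WI³ exactly 1.0, where floating-point equality is taken literally.
- Storey-type q-values are not implemented; BH is used throughout.
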