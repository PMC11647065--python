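# Methods

`mrahc` clusters genetic variants used as instruments for a shared exposure
according to the causal effect(s) they identify on one or more outcomes, in
the multi-sample summary-data Mendelian randomization (MR) setting. This
note records the statistical model, the algorithm as implemented, every
tunable that matters, what the simulator does and does not emulate, and the
design choices made where more than one reasonable implementation existed.

## Model and estimands

For variant j (j = 1..J, mutually uncorrelated) we observe GWAS summary
statistics: the variant–exposure association estimate γ̂_j with standard
error se(γ̂_j), and for each outcome p = 1..P the variant–outcome
association Γ̂_jp with se(Γ̂_jp), measured in samples independent of the
exposure sample (outcome samples may overlap each other). The
variant-specific causal ("ratio") estimate is the P-vector

    β̂_j = Γ̂_j / γ̂_j ,

which converges to the estimand β_j = Γ_j / γ_j. Under causal-effect
homogeneity all β_j coincide; under mechanistic heterogeneity — distinct
causal pathways through sub-components of the exposure, and/or pleiotropy —
the β_j take a small number of distinct values, one per variant cluster,
plus idiosyncratic values for "junk" variants whose pleiotropic effects
follow no shared pathway.

The first-order (NOME) variance of a ratio estimate is
v_jp² = se(Γ̂_jp)² / γ̂_j², giving per-variant weights w_jp = 1/v_jp².
When outcome GWAS samples overlap and the traits are correlated, the P
components of β̂_j are correlated with a constant P×P matrix ρ, so the
per-variant covariance is Σ̂_j[i,r] = ρ_ir v_ji v_jr. By default ρ is the
identity; simulations here and elsewhere show that treating a moderate true
correlation as zero costs little.

## Algorithm

**Step 1 — merge path.** Ward-style agglomeration from J singletons to one
cluster. The distance between clusters S_k and S_l is the Wald statistic
for equality of their cluster effects, D = d′ Ω̂⁻¹ d with
d = β̂ᴵⱽᵂ(S_k) − β̂ᴵⱽᵂ(S_l), where β̂ᴵⱽᵂ is the per-outcome
inverse-variance weighted (IVW) mean and

    Ω̂[i,r] = ρ_ir/(W_ki W_kr) · Σ_{j∈S_k} √(w_ji w_jr)
            + ρ_ir/(W_li W_lr) · Σ_{j∈S_l} √(w_ji w_jr),

with W_Sp the within-cluster weight sums. The diagonal of Ω̂ is exactly
1/W_k + 1/W_l, the familiar sum of IVW variances; this identity is asserted
at run time as a guard on the covariance construction (note that
√(w_ji w_jr) = γ̂_j²/(se(Γ̂_ji) se(Γ̂_jr))). For P = 1 the distance
reduces to the two-sample Wald statistic, and the whole path coincides with
classic Ward clustering of weighted scalars (tested against a reference
linkage implementation). Distances between untouched clusters never change,
so only the merged cluster's row of the distance matrix is recomputed.
Exact ties (relative tolerance 1e−12) are broken toward the pair whose
member-index union has the smallest (min, max) pair — deterministic across
platforms.

**Step 2 — downward testing.** Heterogeneity of a cluster S is measured by
the multi-outcome Cochran Q, which (because the covariance is
block-diagonal across variants) decomposes as

    Q(S) = Σ_{j∈S} (β̂_j − β̂ᴵⱽᵂ)′ Σ̂_j⁻¹ (β̂_j − β̂ᴵⱽᵂ),

with P(|S|−1) degrees of freedom, compared against the (1−ζ) χ² quantile,
ζ = 0.1/ln(n) (natural log; n is the smallest outcome sample size, or an
effective sample size 4/(1/cases + 1/controls) for binary outcomes). The
descent is recursive on the dendrogram: the super-cluster is tested; a
cluster that passes is accepted and frozen; one that rejects is split into
the two subclusters it was merged from, and each is tested in turn.
Singletons pass by convention. We deliberately do **not** use the
alternative reading — testing every cluster of a common dendrogram level
and stopping at the first level where all pass. Under that reading a few
outlying variants absorbed deep inside one branch drag the common level far
down and fragment clusters that had already passed; in simulation this
inflated the detected cluster count badly as precision grew and destroyed
selection consistency, whereas the recursive reading preserves it and is
unchanged on clean instances.

**Outlier removal.** Within each accepted cluster, a variant's individual
Q statistic (its own quadratic-form term, cluster mean held fixed) is
approximately χ²_P. Members with individual-Q p-value below 5% are
outliers; they are removed and Steps 1–2 rerun on the remaining variants,
iterating until no outlier remains (default cap: 25 rounds). All removed
variants form the **junk cluster**. Finally, accepted clusters smaller than
`min_cluster_size` (default 6) are also reassigned to junk: a handful of
stray variants that happen to sit together is weak evidence of a distinct
pathway, and an IVW estimate from so few instruments is of little
inferential value. Set `min_cluster_size=1` to keep every cluster.

**Post-clustering inference.** Each cluster's effect per outcome is the
IVW mean with standard error W_Sp^{−1/2}; 95% CIs use the normal quantile
and are exponentiated for odds-ratio reporting. A joint Wald test of the
P-vector estimate against zero (covariance: the single-cluster Ω̂ term),
at the same level ζ, labels **null clusters**; per-outcome Wald p-values
are reported alongside but do not drive the label, since the hypothesis in
view is "no causal effect on any outcome". Overdispersion is summarized by
I² = max(0, (Q − df)/Q); for clusters with I² > 0 the output additionally
carries multiplicative overdispersion-adjusted standard errors
se·√max(1, Q/df), clearly labelled — a light-weight diagnostic in place of
a full random-effects refit.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n` / `zeta` | — (required) | sample size driving ζ = 0.1/ln(n), or ζ directly; dimensionless p-value threshold |
| `rho` | identity | P×P outcome correlation of the Γ̂ errors |
| `outlier_p` | 0.05 | individual-Q p-value below which a member is an outlier |
| `max_iter` | 25 | cap on outlier-removal rounds (the iteration otherwise runs to convergence) |
| `min_cluster_size` | 6 | accepted clusters below this size are reassigned to junk |

## Simulator

Data are generated directly at the summary-statistic level, which is the
level the method consumes: γ_j ~ U(0.3, 0.5) per allele; γ̂_j ~ N(γ_j,
se_γ²); Γ_jp = β_jp γ_j; Γ̂_j ~ MVN(Γ_j, SρS) with S = diag(se_Γ). Cluster
members share their cluster's effect row; junk variants draw β_jp ~ N(0,
junk_alpha_sd²) independently per variant and outcome. The 12 built-in
designs cross P ∈ {2,3}, K ∈ {1,4}, ρ ∈ {0, 0.2, 0.7}, each with J = 100
variants, 10 junk, and cluster sizes 30/30/15/15 for K = 4 (sizes within
the 90 substantive variants are an assumption). In the K = 4 designs the
first cluster represents a correlated-pleiotropy pathway — its effect
vector arises through variant–confounder effects rather than a causal path;
at the summary level it is observationally a cluster like any other, which
is precisely why clustering alone cannot label mechanisms — and the last
cluster sits at the origin. K = 1 designs have a single zero effect row,
so the only substantive cluster is also a null cluster. Monte Carlo
analyses always treat ρ as zero regardless of the generating value,
mirroring the situation where no correlation estimate is available.

Fixed generator constants (versioned; all overridable per design):
se_scale = 0.07 with per-variant jitter U(0.75, 1.25), se_γ = se_scale/4,
junk_alpha_sd = 0.4, n_nominal = 3×10⁵ (ζ ≈ 0.0079, the same order as a
large binary-outcome effective sample size), K = 4 effect rows
(0.4, 0.5), (−0.5, 0.4), (0.5, −0.4), (0, 0) (third coordinate 0.4, −0.4,
0.3, 0 for P = 3). These were chosen so that the noiseless ratio-estimate
scatter shows four well-separated centers with one null pattern, and so
that cluster separation is 3–5 ratio-SE units — hard enough that clustering
is non-trivial, easy enough that it mostly succeeds.

**What the simulator does not emulate.** Real GWAS features absent here:
linkage disequilibrium between instruments (the method assumes independent
variants; clumping is the user's responsibility), weak instruments
(γ̂ ≈ 5% relative error here, so NOME is benign), winner's-curse selection
of instruments, allele-frequency-dependent standard errors, sample overlap
between exposure and outcome GWAS, and within-cluster effect dispersion
(members share β exactly). Passing simulation checks therefore demonstrates
correctness of the algorithmic machinery and calibration of the selection
thresholds under the assumed sampling model — not robustness to these
real-data violations. One visible consequence: junk variants whose random
effects land inside a cluster's basin are silently absorbed, so the
detected junk count in the K = 4 designs runs below the nominal 10; the
evaluation metrics track how the true junk are handled rather than
penalizing this.

## Evaluation metrics

Per replication: the number of detected substantive clusters; the Rand
index between true and detected labels over true non-junk variants
(junk-assigned variants count as one extra label); the detected junk count
and its overlap with the true junk set; the mean absolute and squared error
between each non-junk variant's assigned-cluster IVW estimate and its true
effect, over variants and outcomes (variants assigned to junk contribute
their own ratio estimate — they still "identify" something, just not via a
cluster); and, for single-cluster results, whether the joint Wald test
labelled the cluster null. Rand-index pair counting is unit-tested against
brute-force enumeration.

## Numerical choices and degenerate inputs

- Ω̂ and the null-test covariance are inverted by solving P×P symmetric
  systems (P ≤ 3 in all supported settings); a condition number above 1e12
  raises an error rather than falling back to a pseudo-inverse — a singular
  Ω̂ signals degenerate inputs (e.g. perfectly duplicated outcomes) that
  the user should see.
- Σ̂_j⁻¹ is computed analytically as diag(1/v_j) ρ⁻¹ diag(1/v_j).
- A variant with γ̂_j = 0 has no ratio estimate and is rejected by name;
  harmonization flips signs of γ̂ and Γ̂ (swapping alleles) so every
  retained variant has γ̂ > 0.
- Allele harmonization across tables uses swap-and-flip, then strand
  complement; palindromic variants are dropped only under `--strict`.
  (How the original analysis resolved allele mismatches is not documented;
  swap-and-flip is the field's standard default.)
- χ² thresholds are cached per degrees-of-freedom; df = 0 (singletons)
  passes with p = 1 by convention.
- All Monte Carlo randomness flows from `numpy` `SeedSequence(seed,
  spawn_key=(rep,))`, so any replication is reproducible in isolation and
  results are prefix-stable in the number of replications.

## Known limitations

- Clusters are reported without uncertainty on the partition itself; the
  procedure is deterministic ("hard" clustering).
- The I²-flagged overdispersion adjustment is multiplicative and crude; a
  random-effects or profile-score refit of overdispersed clusters is out of
  scope.
- Outcome correlations must be supplied by the user (e.g. from LD-score
  regression); the package does not estimate them.
- Direct causal effects between outcomes are not modelled; if present,
  cluster memberships are expected to be stable but estimates are total
  rather than direct effects.
- The problem sizes used in the shipped evaluation (200 replications per
  design; J = 100) keep a full run of the test suite and the acceptance
  script at desk scale; all counts are parameters.
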