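# Methods

## Scope and data model

`germscreen` evaluates germination-stage drought tolerance from a tidy
raw table with one row per (accession, biological replicate, treatment,
technical replicate): dry and 20 h-imbibed seed mass, germinated-seed
counts on days 2/3/4/7 out of seeds sown, and day-7 fresh weight,
seedling length and root length.  Treatments are CK (control, plain
water) and DS (osmotic drought stress).  Technical replicates are
aggregated by arithmetic mean *before* any ratio is formed: the roll is
the observational unit and each roll's morphometrics are already
pooled-seedling means, so the stressed/control ratio is a ratio of roll
means, not a mean of per-roll ratios.

## Traits and drought-tolerance coefficients

The eight traits are AR = (m20 − m0)/m0, GP = g3/n, GR = g7/n,
DT from the day-2/4/7 rates, FW, SL, RL as measured and HL = SL − RL.
Negative AR is legal (seeds can lose mass under osmotic stress);
non-monotone germination counts are a validation error, reported with
the offending record's coordinates.

DT is configurable (`dt_mode`): the default `sum` is the literal
GR2 + GR4 + GR7; `mean` divides by three, keeping DT on the same [0, 1]
scale as the rates.  With cumulative day counts (g2 ≤ g3 ≤ g4 ≤ g7, as
this package validates), the sum necessarily exceeds the day-7 rate;
screens that report DT on a 0–0.4 scale with near-complete control
germination are implicitly using non-cumulative ("newly germinated that
day") rates, which this package does not model.  Both DT modes cancel
identically in the DC ratio up to that scale factor, so the downstream
evaluation is insensitive to the choice.

DCs are stored as fractions (1.0 = no stress response), not
percentages, matching the 0–2.5 range observed in real screens.  A zero
control trait leaves that DC missing rather than infinite; accessions
missing a whole treatment are excluded from the DC matrix and listed in
its metadata.  Day-7 morphometrics of rolls with total germination
failure are recorded as 0, so a fully failed accession gets DC 0 for
every seedling trait — the convention real screens print.

## Descriptive statistics

Summary rows use the sample (n−1) SD — the choice matters little at
n ≈ 500 but is fixed and documented — and CV = 100·SD/mean, undefined
(NaN) at zero mean.  DC correlations are Pearson with two-tailed
p-values, pairwise-complete over missing DCs so an accession with a
single failed trait still contributes its other pairs.

## PCA and factor weights

PCA is performed on the correlation matrix (standardized DCs): the
traits are on heterogeneous scales, and the correlation form makes the
total variance equal the trait count.  Eigenvector signs are fixed so
each component's largest-magnitude loading is positive, making scores
and hence memberships reproducible.  Retention defaults to a fixed
k = 3 components, with `cumulative` (≥ threshold % variance) and
`kaiser` (λ > 1) policies available.  Factor weights are eigenvalue
shares over the retained components, ω_i = λ_i/Σλ_i, identical to
contribution-ratio shares.  Rows with missing DCs are excluded from the
PCA entirely; partial projection of incomplete rows is deliberately not
offered, as screens are complete designs.

## Membership, D, WDC, CDC

Component scores are rescaled column-wise by the linear membership
μ(x) = (x − min)/(max − min); no sigmoid or triangular variants are
offered.  Membership is applied to the component scores as-is, without
reversing negatively loaded components: a component dominated by the
water-absorption DC contributes in that trait's direction.  D is the
ω-weighted membership sum, guaranteed in [0, 1].

Gray relational analysis (Deng): reference and comparison sequences are
min–max normalized by default (`none` is available) — the reference
D is already bounded in [0, 1], and min–max is the common convention in
this literature; Δmin/Δmax are taken globally over all comparison
sequences and elements (`per_comparison` scoping is available);
ρ defaults to the universal 0.5.  The degenerate case of every
comparison equal to the reference yields γ = 1 by convention.
WDC is the γ-share-weighted DC sum; with equal weights it reduces
exactly to CDC, the plain DC mean.

Because the retained component scores are linear in the standardized
DCs and membership is affine, D is an *exact* linear function of the
eight DCs.  A stepwise regression of D on the DCs therefore attains
R² ≈ 1 on complete synthetic screens; real screens, where published
models keep four to six terms at R² ≈ 0.9, involve rounding, rank-based
tie-handling and replicate averaging that break the exact linearity.

## Grade classification

Hierarchical clustering of the one-dimensional D values uses Euclidean
distance with unweighted average ("between-groups") linkage, the tree
cut at k = 5, and clusters relabeled I–V by descending mean D.  Because
1-D average-linkage clusters are contiguous in sorted order, clustering
is run on the sorted values and mapped back, which makes the partition
independent of input order and gives deterministic tie-breaking.  Too
few distinct merge heights (duplicate-heavy input) raises an error
suggesting a smaller k.  The API accepts multivariate input for reuse,
without the sorted-order canonicalization.

## Stepwise regression and prediction accuracy

Selection is classic forward-entry/backward-removal on partial-F
p-values with entry 0.05 and removal 0.10 (the common statistical-
package defaults), ties broken by column order.  These defaults admit
spurious terms at the nominal type-I rate — with seven inactive
candidates roughly a quarter of runs pick up one extra term — so
support-recovery experiments in the test suite use a stricter entry
threshold (0.01); both are configurable.  Per-accession prediction
accuracy is 100·(1 − |obs − pred|/obs), floored at 0, with non-positive
observations excluded; this relative-error definition is stated
explicitly because the field's "prediction accuracy" is rarely defined.

## Cross-replicate BLUP

Model y_ij = μ + rep_j + g_i + e_ij with replicate fixed and accession
random.  Balanced tables use the ANOVA method-of-moments closed form
(equal to REML in the balanced case): σ²_e = MS_residual,
σ²_g = (MS_accession − MS_residual)/r truncated at 0 with a warning,
repeatability h² = σ²_g/(σ²_g + σ²_e/r), and
BLUP_i = h²·(ȳ_i· − ȳ··).  Unbalanced tables fall back to REML via a
linear mixed model.  The mean prediction error compares the
BLUP-adjusted D against each replicate's observed D by default
(`rep_mean` compares against the replicate mean instead).

## Synthetic screen generator

The generator emulates the screen's statistical structure with a single
latent tolerance score t_i ~ N(0, latent_sd) per accession.  Each
trait's DC realization per biological replicate is
clamp(base + loading·t_i + ε, 0, 2.5), where base = 1 − severity ×
trait-sensitivity, ε ~ N(0, noise_sd), and the water-absorption loading
is negative (fast imbibers fare relatively worse under stress) while
all others are positive — reproducing the empirical sign pattern of DC
correlation tables.  Control trait values are drawn around
configurable population means (defaults match a published control-row
profile: AR 0.47, GP 0.82, GR 0.95, FW 0.63 g, SL 16.3 cm, HL 6.3 cm,
RL 10.1 cm); stressed values are the control values times the realized
DC.  Germination counts are sequential binomial thinnings toward
cumulative day targets, so trajectories are monotone and bounded by
construction, and total failure under stress zeroes the seedling
morphometrics.  The per-trait sensitivity defaults place the baseline
DCs at severity 0.75 near observed screen means (root length buffered
at ~0.76, hypocotyl and germination potential hardest hit at ~0.25).

Defaults are 200 accessions × 2 biological × 3 technical replicates ×
40 seeds, latent_sd 1, noise_sd 0.05, |loadings| 0.15–0.20; the
acceptance script runs the full 502-accession scale.  The latent score
is written to a `true_tolerance` column that every pipeline reader
drops; only recovery tests read it.

What the simulator does **not** model: within-roll spatial effects and
filter-paper hydraulics; day-resolved seed-mass series beyond the 20 h
point; negative stressed water-absorption rates (the DC clamp keeps
DS AR ≥ 0, though the trait code accepts negative values from real
data); measured seedling length independent of its parts (DS seedling
length is the sum of the independently thinned hypocotyl and root, so
the seedling-length DC is an emergent mixture of the two rather than an
independent draw); and any genetic architecture beyond the single
latent factor.  Consequently the simulated DC correlation matrix is
more uniform than real screens' (a single dominant component carrying
~90% of the variance versus ~40–70% in practice), and passing recovery
tests demonstrate the pipeline's correctness and internal consistency,
not field performance on real germplasm.

## Problem sizes and numerics

The test suite runs screens of 30–200 accessions and the acceptance
script the full 502; the full pipeline on 502 × 2 × 2 × 3 rows takes a
few seconds.  Weight vectors are validated to sum to 1 within 1e-12;
eigen-decomposition is checked against an independent power-iteration
oracle to 1e-8; report files carry full float precision, console
summaries six significant digits.
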