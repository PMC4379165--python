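# Methods

## Population and data model

A partial NCII (North Carolina design II) population consists of two
groups of inbred parents — group A (e.g. cytoplasmic male-sterile
"female" lines) and group B (e.g. fertility-restorer "male" lines) — plus
the F1 hybrids of a subset of the |A| × |B| possible crosses.  Genotypes
are biallelic markers coded 0/1/2 as copies of the reference allele
(missing allowed); inbred parents carry only codes 0 and 2, so the F1
code at every marker is exactly the parental mean — the package deduces
F1 genotypes rather than requiring them to be assayed, and checks any
provided F1 codes for consistency.  A heterozygous parent code makes the
cross segregate and is rejected with the offending individual and marker
named.  For multi-allelic markers (e.g. SSRs) the intended preprocessing
collapses to the most frequent allele versus the rest; the core model is
strictly biallelic.

## The full genetic model and its encoding

With m markers the model contains, per marker, an additive effect a_j on
the dummy x = code − 1 ∈ {−1, 0, 1} and a dominance effect d_j on the
heterozygote indicator z ∈ {0, 1}, plus four statistical interaction
effects per marker pair j < k: aa = x_j·x_k, ad = x_j·z_k, da = z_j·x_k,
dd = z_j·z_k — so ad(j,k) and da(j,k) are distinct effects.  Total:
2m + 2m(m−1) candidate effects (84,050 for m = 205).

The 0/1 dominance coding (rather than ±1/2) keeps parent rows at z = 0,
which is what makes the population-structure behavior come out right:
in an all-parents mapping population every dominance-related column is
identically zero, so only a and aa effects are estimable there.  The
interactions are statistical products of the main-effect dummies, not an
orthogonalized (Cockerham-style) epistasis decomposition; with unequal
allele frequencies the main and interaction columns are correlated and
the per-effect variance contributions need not be orthogonal.

Missing genotypes are handled two ways: the screening stage simply
excludes the affected individuals from each test, while dense
model-matrix columns mean-impute on each scale (additive: 2f − 1 for
reference frequency f; dominance: the observed heterozygote share), so
no individual is discarded from the joint fit.  Columns with zero
variance are excluded from screening (they are untestable, reported with
p = 1) and can never enter the model.

## Stage 1 — bulked-segregant screening

The extreme 10 % tails of the phenotype (floor(0.1 n) individuals per
tail; ordering by (value, id) so ties resolve deterministically and the
two tails are always disjoint) form the "high" and "low" pools.  For each
candidate effect, a contingency table of the *distinct observed values of
its dummy column* (up to 3 levels for additive-style columns, 2 for
dominance-style) against pool membership is tested by Pearson χ² without
continuity correction; df = levels − 1.  Expected counts are not floored;
the asymptotic test is used throughout, matching the scale of published
screening statistics.  Up to 100 main effects and 100 interaction effects
with the smallest P-values (and P ≤ 0.05) advance.  The α = 0.05 entry
requirement, on top of the caps, stops late iterations from admitting
pure noise once the strong signal has been corrected away.  Both parents
and F1 are pooled when tails are selected.

All 84,050 tests of a pass are computed at once: per-pool level counts of
every pairwise product column reduce to about a dozen m × m indicator
matrix products, so a full screening pass costs milliseconds and the
84,050 columns are never materialized.

## Stage 2 — empirical-Bayes shrinkage EM

The selected q columns form Y = Xβ + Zγ + ε with X the intercept
(β = μ), γ_k ~ N(0, σ²_k), σ²_k ~ Inv-χ²(τ, ω) and flat priors on β and
σ².  Marginally Y ~ N(Xβ, V), V = Σ_k Z_k Z_kᵀ σ²_k + I σ².  Starting
from β̂ = mean(Y), σ̂² = ‖Y − Xβ̂‖²/n and σ²_k on the data scale
(var(Y)/q), the EM iterates

* E-step: E(γ_k) = σ²_k Z_kᵀ V⁻¹ (Y − Xβ);
  var(γ_k) = σ²_k − σ²_k Z_kᵀ V⁻¹ Z_k σ²_k;
  E(γ_kᵀγ_k) = E(γ_k)² + var(γ_k)
* M-step: σ²_k = [E(γ_kᵀγ_k) + ω] / (τ + 2 + 1);
  β = (Xᵀ V⁻¹ X)⁻¹ Xᵀ V⁻¹ Y (V at the updated σ²_k);
  σ² = (Y − Xβ)ᵀ [Y − Xβ − Σ_k Z_k E(γ_k)] / n

until the largest absolute change over (β, σ², all σ²_k) drops below
1e-6 or 1,000 iterations.  Defaults (τ, ω) = (0, 0) make the variance
update E(γ_kᵀγ_k)/3.  Each σ²_k is floored at 1e-10; a component at the
floor reports E(γ_k) = 0, and effects with |E(γ_k)| ≤ 1e-6 after
convergence are treated as excluded.  Z columns are not standardized:
effects are reported on the coded scale.

Two algebraically equivalent linear-algebra routes are implemented: the
default works through the q × q capacitance matrix (Woodbury), never
forming the n × n covariance; a direct dense-V factorization is the
reference route and the two agree to 1e-8 (tested).

Two properties of this EM are worth knowing.  First, it is a *posterior
mode* EM for the variance components: the quantity it ascends is the
marginal likelihood times the Inv-χ² prior.  The marginal likelihood
alone can decrease while the prior shrinks a moderate effect to zero —
this is by design, not a bug; retention effectively requires a
signal of roughly t² ≳ 12, which is what gives the method its very low
false positive rate.  Second, the residual-variance update above is the
method's closed-form shortcut rather than the exact maximizer of the
expected complete-data likelihood, so even the penalized objective is
monotone only up to ~1e-4 near convergence; the tests assert exactly
that.

## Stage 3 — LOD testing

Each retained effect is tested profile-style: LR = 2[logL(full) −
logL(γ_k = 0)], where both log-likelihoods are Gaussian residual
likelihoods with every other converged parameter (β, σ², other γ) held
fixed — no refitting of the reduced model.  Negative LR (possible for an
over-shrunk coefficient) is clipped to zero.  LOD = LR / (2 ln 10);
the significance threshold is LOD ≥ 2.0, boundary inclusive.  The LOD is
invariant to rescaling the phenotype.

## The iterative scan

Screen → fit → test → correct (y′ = y − W b, using the current pass's
estimates of the *newly* significant effects only) → repeat, excluding
already-accumulated effects from re-screening, until a pass adds nothing
or 20 outer iterations.  Finally all accumulated effects are refitted
jointly on the *original* phenotype and LOD-filtered once more; the
report lists main effects first, then interactions, each ascending by
screening P, with marker names, allele frequencies, screening χ²/P, LOD,
the effect estimate and r² = 100·Var(w·γ̂)/Var(y) (population-variance
convention).  The scan is fully deterministic given its inputs.

## Hybrid prediction and combining ability

Every (parent A, parent B) combination gets a predicted genotypic value
v_ij = μ̂ + Σ_k w_k(i,j)·γ̂_k, where the F1 dummy values follow from the
parental codes (a parent missing a QTL genotype falls back to the
parental allele frequency, with a warning).  Observed F1 phenotypes
replace predictions for realized crosses by default (the mixed table is a
deliberate choice; purely predicted tables are available with
`use_observed=False`).  On the completed table, GCA_i = row mean − grand
mean, GCA_j = column mean − grand mean, SCA_ij = v_ij − grand mean −
GCA_i − GCA_j, so grand mean + GCA_i + GCA_j + SCA_ij reconstructs every
cell exactly and each GCA vector and every SCA margin sums to zero.
"BV" — the value a cross is ranked by — is the (predicted or observed)
hybrid value v_ij itself; elite parents are ranked by GCA and elite
crosses by BV with SCA reported alongside.  Unweighted means define GCA
because the completed table is balanced by construction.

## The simulator and what it does (and does not) emulate

`simulate_ncii_population` draws inbred parents marker-by-marker (code 2
with probability equal to the reference-allele frequency, default 0.5 at
every marker, independent across markers and individuals), builds a
partial pedigree by crossing each group-B line to 2 distinct random
group-A lines — cycling group-B lines until the requested F1 count is
reached — and deduces F1 genotypes.  Preset structures: the
725-individual breeding scale (298 + 143 parents, 284 F1), sample-size
series n = 400/500/600 at 1 group-B : 2 group-A : 2 F1 (e.g. 500 = 100 +
200 + 200), all-parents (300 + 300), parents+F1 (150 + 150 + 300) and
F1-only (parents genotyped but unphenotyped).

The default QTL architecture is 8 QTL — 2 additive, 2 dominant, 1 aa,
1 ad, 1 da, 1 dd — all located on markers.  Per-QTL effect sizes are
calibrated from heritabilities via σ²_G(i) = h²_i σ²/(1 − Σ h²_i) with
σ² = 1, and e_i = sqrt(σ²_G(i)/Var(w_i)) using the *realized* population
variance of the QTL's dummy column, so each QTL explains exactly its
target variance share in the simulated sample (an identity the tests
check to 1e-12).  Effect signs default to positive.  Phenotypes are
y = μ + Σ e_i w_i + N(0, σ²).  Dominance-related dummy columns are
positively correlated in mixed parents+F1 populations (they co-indicate
F1 membership), so total phenotypic variance slightly exceeds the
orthogonal-sum value σ²/(1 − Σh²); the variance tests use the exact
decomposition Var(y) ≈ Var(g) + σ².

What the generator does **not** emulate: linkage and recombination
(markers are independent, QTL sit exactly on markers), real allele-
frequency spectra and linkage disequilibrium of a breeding panel,
genotyping error, and shared environmental structure.  Passing tests
therefore demonstrate the statistical machinery under idealized
segregation, not performance on any particular real panel — the original
oilseed data are not distributed, so the published per-locus results are
exercised only through their χ²→P worked examples and the report layout.

`run_experiment` repeats simulate → scan → match (exact descriptor
equality) and reports per-QTL empirical power (share of replicates with
the effect in the final LOD ≥ 2 report), mean and SD of the absolute
bias |estimate − truth| over detecting replicates, and the false
positive rate with denominator (84,050 − number of simulated QTL) =
84,042 for the default architecture.  Replicate seeds derive
deterministically from the base seed.  The shipped experiments use 20
replicates per condition (10 in the acceptance script), a problem size
chosen so the whole evaluation stays interactive on one CPU; trends
(power rising with heritability and sample size, main effects beating
interactions, dd weakest, FPR ≈ 2·10⁻⁴) are stable at this depth.

## Numerical choices and limitations

* Convergence tolerance 1e-6 (max absolute parameter change), 1,000 EM
  iterations, variance floor 1e-10, non-zero threshold 1e-6 — all
  configurable through `EBayesConfig`.
* Screening ties (equal P) break by canonical effect order (a, d per
  marker, then aa/ad/da/dd per pair); extreme-group ties break by id.
* Degenerate inputs: zero-variance phenotypes, all-missing markers,
  overlapping tails, heterozygous parents and non-positive-definite
  covariances all raise informative errors; untestable effects are
  flagged rather than dropped silently.
* The two-stage testing (shrinkage fit, then fixed-parameter LOD) has no
  formal genome-wide error control; the fixed LOD 2.0 threshold is the
  method's pragmatic choice and the simulations quantify its realized
  false positive rate.
* Three-locus interactions, orthogonal epistasis recodings,
  permutation-based thresholds, multi-trait analysis and kinship-based
  genomic prediction are out of scope.
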