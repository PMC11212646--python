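# Methods

## Model and scope

diallelkit analyses complete full diallels: p parents (p ≥ 3), all p²
ordered matings including selfs, r complete blocks (r ≥ 2 for any inference,
since the residual needs (p²−1)(r−1) df). Everything is fixed-effects
(Griffing's Model I): the parents are the population of interest, effects
are constants, and the only random term is the plot error, assumed iid with
variance σ²e. Entry means x_ij therefore have independent errors with
variance σ²e/r, which is the engine behind every standard error and F test
in the package. Blocks are additive (RCBD); missing or unbalanced cells are
rejected at validation rather than imputed, because all estimators are
closed-form projections that assume the complete table.

## Estimation

Griffing Method 1 closed forms and the directional partition are implemented
exactly as stated in the README. Two identities worth recording, because
they are easy to get wrong:

* The adjusted SCA printed formula needs the 1/(2n) coefficient on the
  marginal-sum term. With a bare 1/2 the defining identity
  (ŝ_ij + ŝ_ji)/2 = Griffing ŝ_ij cannot hold (and the units are wrong).
* The exact reconstruction of the mean table from the partitioned effects is

      x_ij = μ + g_i + g_j + ŝ_ij(adjusted)

  with the **symmetric** Griffing GCAs, not μ + g_fi + g_mj + ŝ_ij. The
  adjusted SCA already contains the maternal swing: algebraically
  ŝ_ij(adjusted) = ŝ_ij(Griffing) + r̂_ij and
  μ + g_fi + g_mj + ŝ_ij(adjusted) = x_ij + m_i − m_j. Both forms are
  asserted in the test suite.

The maternal estimator m̂_i = (x_i. − x_.i)/2n and the partition form
(ĝ_fi − ĝ_mi)/2 are the same linear functional; the package exposes both
and tests their exact agreement.

## ANOVA and testing

The plot-level RCBD ANOVA (replications, treatments, residual) is computed
from the balanced closed-form sums; a statsmodels OLS/anova_lm fit serves as
an independent oracle in the tests. The treatment SS on the entry-mean basis
is then partitioned orthogonally:

    SS_GCA = Σ(x_i.+x_.i)²/2p − 2x_..²/p²          df p−1
    SS_Rec = Σ_{i<j}(x_ij−x_ji)²/2                 df p(p−1)/2
    SS_SCA = SS_Treat − SS_GCA − SS_Rec            df p(p+1)/2 − p
    SS_Mat = Σ(x_i.−x_.i)²/2p                      df p−1
    SS_NM  = SS_Rec − SS_Mat                       df p(p−1)/2 − (p−1)

The maternal SS is the quadratic form of the maternal estimator, which makes
the df bookkeeping close (p−1 maternal + the non-maternal remainder equal
the reciprocal df). Every mean square is tested against σ̂²e/r = MS_resid/r
(single error line, Model I); df2 is the RCBD residual df. Zero or negative
SS (degenerate inputs) report F as missing with p = 1. Because the basis of
published combining-ability tables is often ambiguous, the ANOVA carries an
explicit basis flag and can be emitted on the mean basis or the plot basis
(SS × r; F identical).

Standard errors are not transcribed from the literature: each effect
estimator is a fixed linear form in the p² independent entry means, so its
variance is σ²e/r times the squared norm of its coefficient vector, which
the code builds directly (this reproduces Griffing's 1956 Method 1
formulas). A vectorised Monte-Carlo oracle (10,000 error-only tables)
confirms each SE to within 3%. Significance flags are two-sided
normal-deviate tests at 0.05/0.01, with no multiplicity correction — the
conventional annotation style for these tables.

## Variance components

On the entry-mean basis the moment estimators are

    σ̂²e   = MS_resid/r
    σ̂²gca = (MS_GCA − σ̂²e)/2p
    σ̂²sca =  MS_SCA − σ̂²e
    σ̂²rca = (MS_REC − σ̂²e)/2

Negative estimates are truncated to zero and flagged. Under the
fixed-effects reading, each component is defined as the corresponding
quadratic form of the true effects divided by its df (e.g. σ²gca =
Σ(g_i−ḡ)²/(p−1), σ²rca = the mean squared reciprocal deviation): because the
SS are orthogonal projections and the noise contributes df·σ²e/r to each in
expectation, the estimators above are *exactly* unbiased for those
quantities, whatever the true effect configuration. The recovery experiment
exploits this: its reference values are obtained by running the same
decomposition on the noiseless expectation surface, so estimator bias can be
separated from Monte-Carlo error cleanly. (Under a random-effects reading
the expected mean squares would pick up cross-contributions — e.g. E MS_GCA
gains (2(p−1)/p)σ²sca — and different estimators would be needed; Model II
is out of scope.)

Derived parameters: σ²A = 2σ²gca, σ²D = σ²sca, and the phenotypic variance
is composed as σ²P = σ²A + σ²D + σ²rca + σ²e/r where σ²e is itself the
entry-mean error variance. This composition is adopted as the package's
definition because it is the one that closes the published
genetic-parameter table this package was validated against (all eight trait
rows reproduce within print rounding); it treats the reported error column
as already on the mean basis and shrinks it once more by r inside σ²P.
Heritabilities are percentages of σ²P; Baker's ratio is 2σ²gca/(2σ²gca +
σ²sca), reported as 0 when no genetic variance is present; σ²P = 0 makes
the heritabilities undefined (reported missing).

## Heterosis and correlations

MPH and BPH use the standard percentage definitions against the mid-parent
and the direction-favoured parent; the direction convention is
smaller-is-better for the maturity traits (DTT, DTS) and larger-is-better
otherwise, overridable per trait. Crosses whose parental reference is zero
are flagged undefined rather than silently dropped. The correlation grid
(responses: F1 mean, MPH, BPH; predictors: Griffing ŝ_ij, adjusted ŝ_ij,
g_i + g_j, and the directional sum g_fi + g_mj) is computed over the p(p−1)
ordered hybrids by default — straight and reciprocal crosses pooled, which
is the resolution at which the directional predictors carry information — or
over the i<j triangle on request. Pearson r with two-sided t tests;
zero-variance series are reported missing.

## The synthetic generator

`SimTruth` draws (or accepts) effects constrained to the estimators'
identifiable subspaces — g_f, g_m, blocks sum to zero; the symmetric SCA
matrix has vanishing row sums; the antisymmetric non-maternal matrix has
vanishing row sums — and adds a constant selfing offset d on the diagonal
plus iid Gaussian plot error. With σe = 0 every estimator returns its
generating value to machine precision (for d = 0; a nonzero d is absorbed
into the SCA as d(δ_ij − 1/p), which the recovery reference handles by
construction). One seeded generator drives all draws; the same truth always
yields byte-identical data.

Default scenario (one trait, grain-yield scale, q/ha): p = 8, r = 3,
μ = 70, σe = √47.44 ≈ 6.89 (the residual mean square of the validation
study), GCA sd √22.09, SCA sd √271.25, maternal sd 6.0 (matching the
published maternal-effect spread), non-maternal sd 6.8 (so the implied
reciprocal variance 2σ²m + σ²nm ≈ 119 matches the published σ²rca), block
sd 1.26 (back-solved from the replications mean square), selfing offset
−15 (≈20% inbreeding depression of the selfs). The generator emulates a
single balanced environment with additive blocks and homoscedastic Gaussian
errors; it does not emulate genotype×environment interaction, spatial field
trend, error heteroscedasticity across entry types, or epistatic structure
beyond what the free SCA matrix can express — so passing tests certify the
estimation machinery, not robustness of the design to those real-data
features.

Monte-Carlo problem sizes used by the test suite: 1,000 null simulations
for the maternal F-test size (binomial band 0.03–0.07 around the nominal
0.05), 2,000 simulations for variance-component recovery (within 5%),
10,000 error-only tables for the SE oracle, 200 simulations for the
qualitative trend that the directional SCA out-correlates the symmetric SCA
when reciprocal variation is present.

## Numerical and reporting choices

* Validation errors are typed (completeness lists the absent triples;
  duplicates and foreign parents are named).
* Human-readable report CSVs round to 2 decimals, mirroring publication
  style; `bundle.json` stores shortest-repr floats and round-trips
  bit-for-bit.
* F ties/zero denominators: SS clipped at 0, p reported as 1.
* The published-value checks in the tests tolerate one unit in the last
  printed decimal; for the full genetic-parameter closure the printed
  *inputs* are themselves rounded, so the check propagates half-ulp input
  boxes through the (componentwise monotone) formulas by corner evaluation
  instead of pretending the inputs are exact.

## Limitations

Only Griffing Method 1 (complete table with selfs and reciprocals) is
supported — no Methods 2–4, no missing-cell ANOVA, no multi-environment
analysis, no Model II/REML variance components, no Hayman graphical
analysis, and no standard errors for heritabilities. The correlation study
is descriptive (no multiplicity control), and the heterosis module assumes
the parental selfs are measured in the same trial as the hybrids.
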