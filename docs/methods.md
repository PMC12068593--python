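# Methods

## Problem setting

A non-cycloplegic photoscreener reports, per eye, sphere S, cylinder C and
axis (or a status code: `HYP` for hyperopia above the device ceiling, `MYO`
for high myopia, `UNREADABLE` when no measurement registered).  A referral
rule set assigns four positive thresholds per age band (< 4 years, >= 4
years): hyperopia >= h, myopia <= m (m < 0), astigmatism >= a, anisometropia
>= d.  A child fails a category when the worse eye's configured metric
crosses the band threshold, and is referred when any category fails or the
device could not read either eye.

All algebra is done in minus-cylinder form (C <= 0); plus-cylinder input is
transposed as (S, +C, ax) -> (S + C, -C, ax +/- 90) with axis kept in
(0, 180].  The spherical equivalent SE = S + C/2 and the principal meridian
powers (S and S + C in minus-cylinder form) are transposition invariant,
which the property tests enforce.

## Metric convention

Published rule sets state thresholds, not the refraction component they are
applied to.  The package makes the mapping explicit and configurable
(`MetricConvention`); defaults:

* hyperopia: most-plus meridian (= sphere in minus-cylinder form).  The
  device's own behaviour ties its `HYP` code to the sphere, so the sphere is
  the natural carrier of the hyperopia signal.
* myopia: spherical equivalent.
* anisometropia: interocular SE difference (alternatives: sphere difference,
  maximum meridional difference).
* code surrogates (+5.50 / -7.50 D) exist only for contexts that need a
  numeric stand-in; classification treats codes categorically, and a coded
  eye contributes no cylinder or anisometropia information.

Boundary semantics: thresholds are inclusive (>= / <=), age exactly 4.0 years
falls in the >= 4 band, and comparisons carry a 1e-9 tolerance — moot in
practice because all built-in thresholds and fixture values are quarter
diopters, exact in binary floating point.

## Statistics

The six rule sets are applied to the *same* children, so rate comparisons are
paired.  Cochran's Q over the N x k binary flag matrix is

    Q = k(k-1) * sum_j (C_j - T/k)^2 / (k*T - sum_i R_i^2),  df = k - 1,

with Q = 0, p = 1 when every row is constant (degenerate denominator).  For
k = 2 this reduces algebraically to the uncorrected McNemar statistic
(b - c)^2 / (b + c), which the tests verify numerically.  Pairwise post-hoc
comparisons use McNemar's test: exact two-sided binomial p = min(1,
2 P(X <= min(b, c))), X ~ Bin(b+c, 1/2), below 25 discordant pairs, else the
continuity-corrected chi-square (|b-c| - 1)^2/(b+c).  Post-hoc p-values are
reported raw by default (a Bonferroni matrix is available but optional,
matching how such screening comparisons are conventionally reported).

Between-school 2x2 tables use the Pearson chi-square without Yates
correction, N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); when strictly more than
25% of expected cell counts fall below 5 the pipeline switches to Fisher's
exact test, computed by full hypergeometric enumeration in exact integer
arithmetic (two-sided: sum of table probabilities <= the observed one within
1e-7 relative tolerance).  Continuous summaries use Welch's t with
Welch-Satterthwaite df (pooled variant available).  The single-proportion
sample size n = z^2 p (1-p) / e^2 is reported as raw value, floor and
ceiling, since "at least n" phrasing is ambiguous about rounding.
Percentages are rounded half-up in decimal arithmetic (`percent_round`), the
convention that matches printed screening reports, not banker's rounding.

## Cohort reconstruction

Only count tables are available for the study cohort, so the fixture is
*synthesized*: a 308-child cohort whose classification reproduces every
per-criterion category count exactly and the overall referral counts as
closely as integer feasibility allows.

1. **Threshold chains.**  For a category and age band the criteria thresholds
   sort into a chain; the half-open interval between adjacent thresholds (a
   *region*) is flagged by a fixed, monotonically growing set of criteria.
   Region representatives sit at the region's lower threshold: every built-in
   threshold is a quarter diopter, so representatives are exact, always
   attainable with device-step readings, and deliberately exercise the
   inclusive boundary.  (Midpoints would be eighth-diopter values, and the
   top anisometropia region is not realizable above ~1.75 D without
   co-flagging Matta & Silbert hyperopia or myopia.)
2. **Child types.**  A child archetype is a band plus one optional region
   value per category.  A deterministic quarter-diopter scan searches for two
   in-range readings realizing exactly those values; the candidate is
   accepted only if re-classification under every rule set matches the
   intended flags.  Combinations that cannot be expressed without an
   unintended flag (e.g. hyperopia + myopia in one child without the implied
   anisometropia) are excluded by construction.
3. **Joint integer program.**  One MILP (HiGHS via `scipy.optimize.milp`)
   chooses counts per child type.  Hard equality constraints: the 24
   per-criterion category counts and the device-code counts (7 `HYP`, 1
   `MYO`, 2 code-free unreadable children, who count toward every rule set's
   referral but no category).  Union (overall referral) counts enter as
   equalities with penalized slack, so shortfalls surface as reported
   residuals rather than silent adjustments — the overlap structure (which
   categories co-occur in a child) is exactly what makes a union smaller
   than its category sum, and it is recovered, not invented.  Band totals are
   capped at the published 106 / 202.  On the packaged targets the program
   attains zero slack: all six union counts are exact.  A two-stage design
   (per-category allocation, then greedy pairing) was considered and
   rejected: with a band-agnostic allocation the ABCD union cannot be
   reduced enough, because in the >= 4 band every ABCD-flagged astigmatism or
   myopia reading is also AAPOS-flagged; hitting the published unions
   requires placing some astigmatism in the under-4 band where ABCD flags at
   2.25 D but AAPOS only at 3.00 D.  The standalone per-category solver
   (`solve_category_allocation`, tie-breaking toward the >= 4 band and
   smaller magnitudes) remains available for feasibility analysis and raises
   a named infeasibility when targets violate threshold-nesting monotonicity.
4. **Materialization.**  Types expand to records in deterministic order;
   unflagged children (SE +0.50 D, no cylinder) fill the bands.  School
   assignment reproduces the referred-by-school split (41 public / 28
   private) and spectacle quotas (2 / 26, all wearers referred) exactly; the
   stratified per-category counts are approached greedily and reported as
   achieved-vs-target (exact reproduction is generally impossible because
   category overlaps are shared across strata).  Grade, sex and age-band
   margins are filled by quota.  The finished cohort is re-classified and the
   category counts asserted — a mismatch is a hard error, because this cohort
   is the package's acceptance surface.  Identical targets yield
   byte-identical CSV output.

The reconstruction recovers *a* cohort consistent with the published
marginals, not the true one: joint structure beyond the constraints is
unidentifiable, axis values are placeholders, and per-child ages are band
representatives (3.5 / 5.0 years).

Known inconsistencies in the source tables are left as-is rather than
force-fit: the Arthur anisometropia percentage (17/308 = 5.5, printed 5.7),
the two different percentages printed for the same Arnold anisometropia count
of 5, and a stratified anisometropia row (6) that cannot equal the criterion
count (14).  Counts are treated as authoritative throughout.

## Synthetic cohorts

`generate_cohort` draws, per stratum: eye-pair SEs from a bivariate normal
with interocular correlation rho (default 0.9; eye refractions are highly
concordant, and lower values inflate anisometropia far beyond the few-percent
prevalence seen in screening), cylinder magnitudes from Bernoulli(0.7)
presence times a lognormal with median 0.75 D and shape 0.45 (chosen so the
flagged tail >= 1.75 D averages ~2.1 D, the level reported among flagged
children), quantized to device quarter-diopter steps with the sphere
back-computed so the SE draw is preserved.  Stratum defaults mirror the
screened population: public 114 children, SE 0.82 +/- 1.00 D, 11% under
four; private 194, 0.45 +/- 0.67 D, 48% under four; code rates 7/308, 1/308,
2/308.  Per-child SE for moment estimation is the two-eye mean; with rho =
0.9 its SD is sqrt((1+rho)/2) ~ 0.975 of the per-eye SD, well inside the
0.05 D recovery tolerance at n = 5000.

The generator emulates the marginal structure the analysis assumes; it does
not model repeat captures, axis anatomy, age-refraction dependence, or
within-school clustering — so passing tests demonstrate correctness of the
pipeline on such populations, not validity of the clinical thresholds.

## Problem sizes and determinism

Reconstruction enumerates ~460 child types and solves a MILP with ~470
integer variables and 35 constraints in well under a minute; property tests
use 1000 simulated children for dominance and 10 x 10000 for parameter
recovery.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); the reconstruction path contains none.
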