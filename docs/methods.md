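# Methods

## Design and assumptions

The unit of analysis is the complete case-parent triad genotyped at a
window of linked X-chromosome SNPs: father, mother, and an affected child.
Three assumptions underpin the test:

1. **Exact phase.** No recombination occurs within the window (windows are
   a handful of neighboring SNPs), so the daughter's paternal haplotype is
   the father's haplotype and phasing reduces to integer subtraction.
   Sons' haplotypes are maternal and read directly.
2. **Mendelian transmission** of haplotypes in the source population, and
   no effect of the variants on fetal survival or parental fertility.
3. **Parental haplotype exchangeability (PHE).** Within a couple, each of
   the three carried X haplotypes is equally likely to be the father's.
   PHE is weaker than Hardy–Weinberg equilibrium: it tolerates admixed or
   stratified populations as long as mating is haplotype-symmetric within
   them. PHE is what licenses treating the father's haplotype as a third
   exchangeable "draw" and is the source of the method's extra power
   relative to transmission-only tests.

Pseudo-autosomal and X-transposed regions are out of scope (they recombine
with the Y), as are multiplex families and EM-style handling of missing
genotypes.

## Phasing

For a son: M1 = child, M2 = mother − child, F = father. For a daughter:
M1 = child − father, M2 = mother − M1, F = father. Any result outside
{0, 1} is a Mendelian inconsistency; the family is excluded *for that
window only* and counted. Window-local (rather than study-wide) exclusion
maximizes data use and is the package's choice where the design was open;
the same applies to families with a missing call inside the window.
Phasing is deterministic, elementwise, and covered by an exact round-trip
property test (compose genotypes from any haplotype triple, re-phase,
recover the triple, window widths 1–8).

A family is **noninformative** iff F = M1 = M2; such strata are dropped
(all three alternatives would be identical).

## Risk sets and dosage coding

Sons yield alternatives {M1}, {M2}, {F} (case {M1}); daughters yield the
three unordered pairs of {F, M1, M2} (case {F, M1}). Alternatives are
stored case-first with controls in lexicographic order purely for
reproducible output; the conditional likelihood is order-invariant
(tested).

Model columns are defined by the **codebook**: parental haplotype
frequencies are estimated by counting all three parental haplotypes per
family with equal weight (the simplest unbiased choice under PHE, where a
weighting rule was not otherwise dictated). Haplotypes with frequency
strictly below the pooling threshold (default 0.01, a proportion) form a
single pooled "rare" nuisance column — also when only one haplotype is
rare. Within-stratum dosages sum to a constant, so one common haplotype
must serve as reference; the package uses the most frequent (ties broken
by haplotype order). The choice is cosmetic: the LRT χ² and p are
reference-invariant (tested).

Male dosage coding defaults to **double** (a male's single haplotype
counts as two copies), equating male risk with homozygous-female risk;
"single" coding and boys-/girls-only analyses are options. The PHE test
always uses single coding since each of its alternatives carries exactly
one haplotype.

Optionally (`allow_missing_parent_boys`, off by default) single-parent
families with an affected son enter as two-alternative strata: the
available parent's untransmitted (mother present) or own (father present)
haplotype is the single pseudo-brother. Dyads contribute strata only;
codebook frequencies and the PHE test use complete triads.

## Fitting and the LRT

The exact conditional log-likelihood (a 3-term, occasionally 2-term,
log-softmax per stratum) is maximized by Newton–Raphson with analytic
score and information and step-halving. The per-stratum likelihood is
concave, so convergence is routine: tolerances are max |score| < 1e-8 or
max parameter change < 1e-10, at most 50 iterations (all configurable in
code; the reference analysis environment did not specify any, so these
are the package's own, deliberately tight for a concave problem). A
coefficient whose column never varies within any stratum has zero
curvature at the origin; it is frozen at 0, flagged `inestimable`, and
the result status is `degenerate` (the likelihood does not depend on it).
Fitted |β| > 10 triggers a `SeparationWarning` (monotone likelihood).

The global test is χ² = 2(ℓ_alt − ℓ_null) with df = (#common − 1), upper
tail of the χ² distribution. The null model keeps only the pooled-rare
column; when no haplotype is rare the null is the empty model with
ℓ = −n ln 3, the natural limiting case. Fewer than two common haplotypes
is a `DegenerateWindowError` (alternative and null coincide). The exact
likelihood is verified against a scalar enumeration oracle to 1e-12, and
the Newton optimum against a dense grid search on one-column models.

## PHE test and sex decomposition

The PHE diagnostic refits the same machinery with the father's haplotype
as "case" versus the mother's two as controls (valid under the global
null and absence of maternally-mediated effects). The sex decomposition
augments the PHE model with haplotype × offspring-sex interaction columns
and reports the interaction LRT (df = number of model columns): a fetal
effect enriches mothers of affected boys but fathers of affected girls,
so it loads on the interaction; a maternal effect (or a genuine PHE
violation, e.g. ethnically asymmetric mating) produces a main asymmetry
without interaction. The reported flags ("consistent with fetal effect",
"consistent with maternal effect or PHE violation") are qualitative
guides at a configurable α (default 0.05) — an interpretive framework,
not an automated conclusion. Both main-effect and interaction variants
are provided because the data analysis that motivated the diagnostic can
be read either way.

## Scan, correction, and diagnostics

SNPs are filtered on parental minor-allele frequency (default: strictly
greater than 0.05; one X per father, two per mother; the minor allele is
the less frequent parental allele, ties at 0.5 broken toward the
lexicographically smaller label). Windows are consecutive sets of
`window_width` (default 4) SNPs in panel (map) order; S SNPs give
S − (W − 1) windows and the family-wise Bonferroni threshold is
α / (number of windows), counting all windows attempted, degenerate or
not — matching the convention "number of SNPs minus 3" used for published
thresholds. QQ plots use expected quantiles −log10((i − 0.5)/n), the
standard convention.

The informative-missingness diagnostic cross-tabulates genotype at one
locus against call success at another, per family role. Because only raw
counts were ever published for this phenomenon, the package attaches a
defensible screen of its own: a two-sided Fisher exact test on the
collapsed carrier-status × missingness 2×2 (rows missing at the genotype
locus excluded), per role and pooled. Fisher's test is conservative, so
under independent missingness the flag rate sits at or below the nominal
level (tested).

## Simulator

`draw_families` draws, per family: a subpopulation (mixing proportion
`subpop_mix`), three haplotypes i.i.d. from that subpopulation's table,
a uniformly random allocation of one haplotype to the father (PHE holds
by construction), a fair-coin maternal transmission, and child sex
Bernoulli(`sex_ratio`, default 0.5). Ascertainment of an affected child
is rejection sampling with weight baseline(subpop) × RR(child) ×
RR_maternal(mother), normalized by the global maximum — absolute baseline
risks cancel, only ratios matter.

Built-in conditions: two subpopulations with per-locus minor-allele
frequencies 0.3 and 0.2 at four SNPs (haplotype frequencies are the
products, e.g. 1100 ↦ 0.3·0.3·0.7·0.7 = 0.0441); the stratified null
mixes them 50:50 with a 4-fold baseline-risk ratio (the mixing proportion
was not dictated anywhere, so the package defaults to 0.5, which
maximizes stratification; it is configurable). Risk scenarios designate
1100 as the risk haplotype with R_B = R_G2 = 1.5 and R_G1 = √1.5
(log-additive in girls); scenarios B and C add 1101 at R = 1.2 and 1/1.2
respectively, read log-additively for consistency with the explicit
square root in scenario A (an override accepts arbitrary
(R_B, R_G1, R_G2) triples). `rescale_frequencies` sets the risk
haplotypes' total frequency preserving their internal 0.0441:0.0189 =
7:3 ratio and rescales the rest proportionally. A `maternal_risk_map`
multiplies the ascertainment weight per maternal copy, for studying the
PHE diagnostic's behavior under maternally-mediated effects.

Datasets are degraded to unphased genotypes before analysis, so every
study exercises the full phasing path. Randomness is a single seeded
generator with per-dataset substreams spawned from the seed, making
results reproducible and order-independent. `run_study` additionally has
a vectorized array pipeline (integer haplotype codes end to end); it is
held equal to the per-family object pipeline by tests (χ² agreement to
1e-8 on shared data).

What the simulator does **not** emulate: genotyping error, informative
missingness, linkage disequilibrium beyond what the haplotype table
encodes, multiplex families, sibling genotypes, or sex-specific baseline
risks. Passing simulation tests therefore demonstrate the statistical
calibration and power of the method under clean data, not robustness to
the data-quality pathologies the missingness diagnostic exists to catch.

## Validation problem sizes

The validation suite uses 1000 families per dataset (the size of the
method's reference simulation studies) with 1000 datasets for type-I
error, 200 datasets per point for power and coefficient recovery, and
2000 replicates for the PHE p-value uniformity check; sex-decomposition
power runs use a risk-haplotype frequency of 0.2, where the parental
asymmetry is comfortably detectable at 1000 families. These sizes are the
package's chosen trade-off between Monte-Carlo error and run time.
Observed operating characteristics (recomputed by `scripts/acceptance.py`
and the test suite, not quoted): type-I error within 3 binomial SEs of
0.05 with and without stratification; mean fitted risk coefficient within
3 Monte-Carlo SEs of ln(1.5)/2; power monotone in sample size.

## Known limitations

* Complete triads only (apart from the optional boy-dyad extension);
  no EM for missing genotypes, no mother-daughter dyads.
* No covariates, no robust variances, no exact conditional inference —
  asymptotic χ² only. At a few hundred families with many common
  haplotypes the χ² approximation is visibly imperfect in the far tail;
  at 1000 families it is clean (the uniformity test above).
* The rare-haplotype pool is a nuisance class: its coefficient has no
  interpretation, and a signal carried entirely by rare haplotypes
  surfaces only through the pooled column.
* Windows are fixed-width and position-blind (panel order); no LD-aware
  windowing.
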