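# Methods note

This note records the modelling conventions, numerical choices and known
limitations of the package. It states what the code computes; empirical
claims are limited to what the test suite verifies.

## Screening cascade

The cascade is a conjunction of per-entity predicates evaluated in a fixed
stage order (`strong_validation`, `lncrna_targets`, `tissue`,
`degree_and_known`, `pd_gene_link`, `specificity`, `cis_pairing`). Because
each stage only removes entities, stage order affects the audit trail
(which stage is blamed for an elimination) but not the surviving set; the
test suite verifies survivor-set invariance under stage permutations and
equivalence with a brute-force single-pass conjunction over all
(lncRNA, miRNA, gene) triples.

Conventions:

* All score gates are strict (`>`), so a score exactly at the threshold is
  eliminated; the gap gate is strict (`<`), so a gap of exactly 50,000 bp
  is eliminated. Boundary behaviour is pinned by unit tests.
* Genomic coordinates are 0-based half-open. The gap between loci A and B
  on the same chromosome is `max(0, max(startA, startB) − min(endA, endB))`,
  which is 0 whenever the loci overlap or abut; loci on different
  chromosomes have infinite gap and never pair.
* The degree of a lncRNA counts only interactions with miRNAs that
  survived stage A and whose interaction score passes the stage-B gate —
  degree is evaluated against the screened universe, not the raw database.
* "Known PD lncRNA" and "excluded disease" use the disease-association
  table with configurable labels; the PD label itself is a `ScreenConfig`
  field rather than a hard-coded string.

## Comparative CT (2^−ΔΔCt)

Technical replicates are collapsed by the mean, with the replicate SD
reported and flagged above a configurable bound (default 0.5 cycles). For
multi-reference targets, ΔCt subtracts the arithmetic mean of the
reference Cts, equivalent to normalizing by the geometric mean of
reference quantities on the linear scale. ΔΔCt subtracts the
baseline-group mean ΔCt, making the baseline geometric-mean rq exactly 1;
group dispersion is reported as mean ± SEM of rq, a convention chosen for
comparability with common qPCR reporting, not because rq is symmetric.

## Adaptive hypothesis testing

Test selection: all groups must pass the D'Agostino–Pearson normality
test (α = 0.05) to use the parametric branch, and groups smaller than 8
observations are treated as non-normal because the omnibus test is
unreliable there; a group with zero range also forces the nonparametric
branch. Two groups then get an unpaired t test (with its standard CI) or
a Mann–Whitney U test with a Hodges–Lehmann shift estimate and a
distribution-free CI based on the normal approximation over sorted
pairwise differences. Three or more groups get one-way ANOVA with Tukey's
HSD, or Kruskal–Wallis with Dunn's post hoc (tie-corrected z statistics on
mean ranks, Bonferroni family correction). Effects are always reported as
second group minus first group of the comparison label.

Data-driven test selection makes the realized size of the procedure
deviate slightly from the nominal α; the acceptance suite checks only
that the type-I error over 2000 null simulations at the study design lies
in [0.025, 0.085], not that it equals 0.05.

## ROC

The AUC is computed through the rank/U-statistic identity (ties counted
half), so AUC = U/(n1·n2) holds to machine precision on tie-free data —
this is asserted to 1e-12 in the tests. When the raw AUC is below 0.5 the
orientation is flipped and flagged, reflecting that a marker that is
consistently lower in cases is equally diagnostic. Under a binormal model
with common SD σ and mean shift δ the population AUC is Φ(δ/(σ√2)); the
simulation tests verify concentration of the empirical AUC around this
closed form.

## Seed sites and reporter assays

The scanner reports canonical site classes only (6mer, 7mer-A1, 7mer-m8,
8mer), assigning each core match its maximal class: the core requires
exact Watson–Crick complementarity of target positions c..c+5 to miRNA
positions 2–7, the m8 upgrade requires the base 5' of the core to pair
miRNA position 8, and the A1 upgrade requires an adenine opposite miRNA
position 1 regardless of pairing, per the canonical targeting model.
G:U wobbles, bulged sites and 3'-supplementary pairing are out of scope.
T and U are interchangeable and case is ignored.

Reporter wells are normalized as Renilla/firefly (the configuration can
swap channels for the opposite vector design); percent change versus the
negative control is `100·(1 − mean ratio / mean NC ratio)`, so positive
values are inhibition. Because every construct is tested against the same
control wells, reported p-values are Bonferroni-corrected across the
tested conditions by default.

## Synthetic generators

Defaults encode the study design (20 controls; 38 patients split 10 stage
I, 17 stage II, 10 stage III, 1 stage IV; six markers with group shifts;
70% wild-type reporter inhibition). Choices made for realism and their
limits:

* Ct noise is additive Gaussian on the cycle scale: per-sample biological
  noise (default SD 0.5 cycles) shared across a gene's replicates, plus
  per-well technical noise (default SD 0.1). With half-cycle marker
  shifts this yields expected AUCs near Φ(0.5/(0.5·√2)) ≈ 0.76, in the
  range reported for blood markers of this kind; the defaults are the
  package's own calibration choice, not fitted values.
* Reference genes are generated shift-free; violations of this assumption
  (reference instability) are not modelled.
* Demographics use truncated normals for age and BMI, a moment-matched
  log-normal for disease duration (right-skewed, strictly positive), exact
  per-group sex counts, screening-consistent cognitive scores (MoCA 26–30)
  and stage-banded motor-score percentages.
* Reporter noise is multiplicative log-normal with unit mean per channel,
  so zero CV recovers the planted inhibition exactly and the ratio of two
  noisy channels stays positive.
* Sequence backgrounds are rejection-sampled to contain no spurious seed
  site for the chosen miRNA before the single site is implanted; mutants
  shuffle the site window until no site class survives there.
* Knowledge-base decoys each violate exactly one cascade predicate while
  satisfying all others, so each decoy pins the elimination stage that
  must catch it.

Generators are deterministic functions of the configured seed
(`numpy.random.default_rng`); identical configurations produce
byte-identical output files.

## Known limitations

* The cascade models the screen as deterministic set logic over a static
  knowledge base; it does not model database noise, annotation lag, or
  probabilistic evidence weights.
* The nonparametric CI for the two-group shift uses a normal
  approximation for the rank of the selected pairwise differences, which
  is slightly liberal for very small samples.
* ceRNA stoichiometry, expression-level coupling between triad members,
  and miRNA transfection efficiency in the reporter model are not
  simulated.
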