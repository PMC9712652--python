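# Methods

## The problem and the design

Severe tinnitus is an extreme-phenotype design problem: the trait is
common and heterogeneous, so cases are restricted to the severe end of
the handicap distribution (THI ≥ 58) to concentrate rare-variant signal,
and the sequenced cohort is small (tens to ~100 genomes). There is no
matched sequenced control cohort; instead, case allele counts are
compared against external population reference panels that publish
allele (or carrier) counts — a SweGen-style national panel and
gnomAD-style frequency tables. `tinvar` implements everything downstream
of variant calling and annotation for this design: variant
classification, per-gene collapsing burden tests with cross-cohort
replication, structural-variant prioritization and constrained-region
burden, clinical subgroup comparisons, and a minimal co-expression step.

## The burden statistic

Rare qualifying variants (per class: LoF or missense; MAF < 0.01 in
every supplied panel) are collapsed per gene into allele counts
a (cases) and c (panel) against allele numbers 2N_case and 2N_panel.
The 2×2 table (a, 2N_case−a; c, 2N_panel−c) is tested with the Pearson
chi-squared statistic on 1 df without continuity correction; the named
"Wald chi-squared" collapsing test is implemented as this statistic plus
a Wald interval on ln OR, since the test's cell construction is the only
part the name pins down. Numerical choices:

* **Zero cells.** The Haldane–Anscombe +0.5 correction is applied to all
  four cells for the OR and its CI only; the chi-squared always uses raw
  cells. This keeps the p-value and the effect estimate decoupled — a
  correction chosen for estimability should not move significance.
* **Degenerate tables** (a zero row or column margin) return χ² = 0,
  p = 1, and for SV tables the OR is reported missing. No significance
  is fabricated from empty data.
* **Enrichment** is p < α (default 0.05, unadjusted) with OR > 1.
  Bonferroni/Benjamini–Hochberg columns are available behind a flag and
  off by default, matching how such screens are usually reported.
* **Counting modes.** SNV collapsing counts alleles (2N chromosomes);
  SV tests count carriers (samples), the unit in which reference panels
  publish SV frequencies. Both modes sit behind one flag.
* **Ordering.** Results sort by p ascending, then OR descending, then
  gene symbol — deterministic reports under ties.

Replication is deliberately permissive, mirroring practice in
multi-panel screens: a gene (per class) replicates when it is enriched
against *at least one* panel in each of the discovery and replication
cohorts; the output records which comparisons supported it.

## Classification thresholds

All boundary semantics are fixed and tested: rare ⇔ panel frequency
< 0.01 (a variant absent from a declared panel counts as frequency 0;
exactly 0.01 is common); damaging ⇔ CADD phred strictly > 20 (missing
score is not damaging); gene-level intolerance ⇔ pLI ≥ 0.9 or
LOEUF < 0.5; SV constrained-region overlap ⇔ an intersected gene with
pLI > 0.9 *and* LOEUF decile bin < 2 (strict on both — the SV-level
convention differs from the gene-level one, and both are kept as their
sources state them). The per-cohort frequency floor 1/(2N) — the
smallest nonzero allele frequency a cohort of N diploid samples can show
— is computed as an annotation only; it never drops variants, because
whether it was ever used as an exclusion rule is not decidable from the
available description.

## SV prioritization

Stages are pure predicates applied in a documented order (size window →
blacklist → known-SV concordance → ACMG rubric → constraint/rarity →
burden); composition equals joint application, which is tested. Two
different overlap conventions are intentional: the 66% artifact rule is
one-sided coverage of the call by the blacklist *union* (fragmenting a
blacklist region cannot change the decision), while the 99% known-SV
rule is reciprocal overlap, |∩| / max(|a|, |b|), type-matched. "More
than 66%" is strict, "overlap of 99%" is inclusive, and the 1 kb–1 Mb
window is inclusive at both ends. Ultra-rare is reference carrier
frequency ≤ 0.001 — the resolution of a 1000-sample panel — with the
boundary inclusive; this cutoff is a package definition, made explicit
because the concept is used in the field without a standard value.

The ACMG-style classifier is a declarative rubric
(`tinvar/data/acmg_rules.yaml`): ordered evidence-pattern → class rules,
first match wins, fall-through class 3 (uncertain significance).
Benign-region overlap → class 2; documented dosage-sensitive loss →
4–5; constrained-gene or protein-coding overlap → 3. Classes 3–5 are
retained for analysis. This is deliberately *not* the full Riggs et al.
point system: the rubric actually applied by annotation engines is
itself an adaptation, and a rules file makes the operative logic
explicit, configurable and testable. Evidence keys not declared in the
rules file raise a configuration error, so a typoed flag cannot silently
downgrade a call.

## Clinical comparisons

Chronic inclusion is TFI ≥ 48, severity THI ≥ 58 (both inclusive; where
the two published statements of the THI cutoff disagree, the table
footnote that operationally defines the subgroup is followed). Every
non-missing duration category in the vocabulary already encodes > 6
months, so chronic selection filters on TFI alone and keeps records with
missing duration. Categorical comparisons use the same raw-cell 2×2
chi-squared as the burden stage, with a Fisher exact fallback (recorded
in the output) when any expected cell is below 5. Continuous comparisons
use the Welch t test — the unequal-variance form is the safer default
when pooling is unjustified — with Shapiro–Wilk p-values recorded per
group. Displayed proportions are round(100·count/total). A comparison of
a severe subset against its superset cohort can be computed as published
tables print it, but the output flags the non-independence; those
printed p-values are not treated as recomputable targets because the
underlying test construction is not stated.

## Co-expression

Per gene, Pearson correlations between all probe pairs across regions;
probes supported by a significant positive correlation (two-sided
p < 0.05 by default) are selected, and co-expressed regions are those
where every selected probe of every queried gene exceeds the expression
threshold (each probe's own row median by default). Both cutoffs are
explicit parameters because no standard values exist for this step;
zero-variance probes yield missing correlations rather than errors.

## The synthetic-data generator

The generator emulates the study's conditions so that every downstream
stage has a testable ground truth: 97 cases with a severe subset of 34
(a random subsample — same genetic model, different clinical model), a
replication cohort of 147, a 1000-sample reference panel, ~200 genes
tiled at fixed offsets on one pseudo-chromosome, and an SV call set with
a planted recurrent deletion at carrier frequencies 0.216 (cases) /
0.235 (severe) / 0.017 (reference) — the effect size of the strongest
published constrained-region deletion.

* **Frequencies.** Each variant has a latent population frequency drawn
  from Beta(0.2, 50) (rare-skewed: > 80% of draws below 1%). The panel
  reports Binomial(2·n_ref, f) draws; case genotypes are sampled per
  allele under Hardy–Weinberg from the *latent* frequency. Sampling
  cases from the latent truth rather than from the observed panel
  frequency matters: it makes case-vs-panel an honest two-sample
  problem, and the burden test's measured type-I error sits at ~0.045–
  0.06 at α = 0.05 on 2000 null genes; conditioning cases on the
  observed panel draw instead makes the test measurably conservative
  (~0.035).
* **Planted enrichment.** For an enriched gene, the collapsed latent
  frequency F of its rare variants of the targeted class is pushed
  through the odds-ratio identity f_case = OR·F / (1 − F + OR·F) and the
  implied scale factor is applied uniformly to that class's variants, so
  the configured OR is the estimand of the downstream collapsing test.
  A target OR that would push any per-variant frequency above 1 is a
  configuration error.
* **Sites per gene.** Default 30 variant sites per gene, putting the
  collapsed rare missense frequency at a median of ~0.02. This reflects
  the large, heavily targeted constrained genes this design nominates
  (calcium-channel and navigator genes with hundreds of annotated rare
  sites), whose published collapsed ORs carry confidence intervals far
  too tight to arise from a handful of sites. At the qualifying boundary
  (collapsed frequency exactly 0.01) the 2×2 test's power against OR 4
  is only ~0.8 with 97 cases, so a generator whose enriched genes sit
  mostly at that boundary describes a different — and weaker — study
  than the one emulated.
* **SV placement.** Background calls are slot-confined: an SV overlaps a
  constrained gene iff it was targeted at one, so ground-truth constraint
  labels are exact, at the cost of capping non-targeted SV lengths at
  one gene slot (100 kb). Artifact calls are planted inside the
  blacklist; a configurable fraction of calls is withheld from the
  known-SV database to exercise the concordance filter.
* **Clinical model.** Severe subjects draw THI uniformly from [58, 100],
  the rest from [0, 57]; everyone meets TFI ≥ 48. Comorbidity flags are
  Bernoulli with severity-conditional probabilities whose defaults are
  the published severe/non-severe rates (e.g. hyperacusis 32/34 severe,
  35/63 non-severe).
* **Determinism.** Every artifact draws from its own named, seeded
  stream; identical config + seed gives byte-identical outputs.

What the generator does **not** model — and hence what passing tests do
not establish about real data: linkage disequilibrium and haplotype
structure, population stratification between cases and panel,
sequencing/genotyping error and coverage bias, annotation error
(consequence or frequency misassignment), relatedness, and real gene
length/constraint correlations. Calibration results here say the
statistic is implemented correctly under its own assumptions, not that
case-vs-panel comparisons on real cohorts are free of stratification or
batch confounding — which they are not, and which is why the published
design leans on replication and constraint filters.

## Problem sizes used in validation

The shipped checks use 2000 null genes for calibration, 200 qualifying
replicates for the OR-4 power study (30 genes each), 200 replicates for
the SV ranking study, 1000 random tables/interval configurations for the
oracle comparisons, and 100-record fixtures for round-trips. These sizes
give the binomial bands quoted above while keeping the full validation
run in the tens of seconds on one CPU.

## Known limitations

* Reference panels are treated as fixed external truths; panel
  mis-annotation or ancestry mismatch propagates directly into ORs.
* No covariate adjustment, kernel tests, or relatedness correction —
  collapsing against a panel cannot use them. Published small-count SV
  p-values cannot be reproduced exactly from printed carrier counts by
  any standard 2×2 test; only frequencies and the clearly significant
  row are treated as recomputable.
* The ACMG rubric is a simplification by design (see above).
* VCF support covers the annotated-cohort subset of the spec (GT fields,
  per-ALT INFO, multiallelic splitting) — not phasing, breakends, or
  symbolic alleles beyond what DEL/DUP tables need.
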