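# Methods

## The analysis model

The package analyses rare coding variation in a fixed screening panel of
25 genes (24 genes with established loss-of-function evidence in GnRH
deficiency plus the delayed-puberty candidate *IGSF10*) across four
cohort groups: Kallmann syndrome (KS), normosmic CHH (nCHH), delayed
puberty (CDGP) and population controls. KS ∪ nCHH is pooled as the CHH
case group. The unit of analysis is the variant–proband observation; the
pipeline is deterministic and rule-based — nothing is estimated from the
data being classified.

### Filtering cascade and mutation definition

1. **Genotype quality.** Calls with GQ < 50 are excluded (threshold
   inclusive at 50; calls with missing GQ are dropped and tallied).
2. **Consequence.** Raw annotation terms (SnpEff / Sequence Ontology
   vocabulary) map to {missense, inframe_indel, frameshift, stop_gain,
   splice_candidate, other}; `other` (synonymous, unmapped terms) is not
   analysed further. Essential splice donor/acceptor disruptions map to
   `splice_candidate` directly; other intronic terms only survive via the
   splice filter below.
3. **Mutation rules**, in precedence order, all requiring rarity
   (matched-population reference MAF < 1%; a variant absent from the
   reference is treated as MAF 0, i.e. private):
   in-vitro loss of function (overrides predictor verdicts but not
   rarity) → rare PTV (frameshift, stop gain, splice candidate) → rare
   missense with ≥1 of 2 predictor verdicts `damaging`. Missing verdicts
   count as not damaging, since the missense rule demands a positive
   prediction. When several reference populations are configured for one
   group, the maximum MAF is used (conservative rarity).

### Splice-site filter

An intronic variant is retained when |distance to the nearest exon
boundary| ≤ 6 bp and the splice-site score changes by at least 20%
relative to wild type, |s(mut) − s(wt)| / |s(wt)| ≥ 0.20, in either
direction. Design choices: the threshold is inclusive; the change is
direction-agnostic (a strengthened site can also disrupt splicing, and
"±20%" does not specify a direction); a degenerate wild-type score of 0
never retains (conservative) and is logged. The scoring model is an
interface over per-position log-odds matrices with maximum-entropy-model
window conventions (donor: 3 exonic + 6 intronic nt; acceptor: 20
intronic + 3 exonic nt). The shipped baseline is a PWM built from
canonical donor/acceptor consensus base frequencies, authored here as a
synthetic stand-in — the genuine maximum-entropy parameter tables are
externally distributed data and no result in this package depends on
their specific values. Matrices round-trip through a `pos × A/C/G/T` TSV.

### Zygosity and architecture

Per (proband, gene): a homozygous mutation ⇒ biallelic; ≥2 heterozygous
mutations ⇒ biallelic under the compound-heterozygote presumption
(cohort sequencing is unphased; `presume_compound_het=False` demotes such
pairs to monoallelic for sensitivity analysis); one het or hemizygous
call ⇒ monoallelic. Hemizygous calls are only valid for male probands in
X-linked genes and contribute one allele. Per proband, the count of
mutated genes (a biallelic gene counts once) maps 0/1/≥2 →
none/monogenic/oligogenic; one biallelic plus one monoallelic gene is
therefore oligogenic. Allele tallies: het/hemi = 1, hom = 2; alleles
inspected per gene = 2N (autosomal) or 2F + M (X-linked). The digenic
matrix counts probands per gene pair; a proband with k ≥ 2 mutated genes
contributes to all C(k, 2) pairs.

### Exact statistics

`fisher_two_sided` implements the minimum-likelihood two-sided
convention: p = Σ P(T) over all tables T with the observed margins whose
hypergeometric point probability is ≤ that of the observed table, with a
relative tie tolerance of 1e-7. Point probabilities are computed in log
space (log-gamma) and renormalised after a max-shift, so reference
denominators of ~70,000 alleles are numerically stable. A table with a
zero margin returns 1.0. The RVA (rare-variant association) test
collapses each gene to (mutated alleles, alleles inspected) in cases vs
an aggregated reference; fractional reference totals (averages of
alleles genotyped across a gene's sites) are rounded to the nearest
integer before testing — an exact test needs an integer table and the
perturbation is at most half an allele, logged when it occurs.
Bonferroni correction (α / n tests) applies to the per-gene RVA family
only (n = panel size, 0.05/25 = 0.002), not to the handful of
cohort-level contrasts. PTV enrichment contrasts the PTV / non-PTV
composition of case vs reference mutation sets; the pLI stratification
contrasts PTVs in high-constraint genes (pLI ≥ 0.9) against the rest,
excluding (and counting) PTVs in genes without a pLI value. The private
fraction deduplicates by variant id — a recurrent mutation counts once.

## The synthetic-cohort generator

The generator emulates the study design; it is the package's test bed,
not a model of biology.

* **Coupling model.** Genes are visited in panel order; a gene mutates
  with probability f_g until the first event, and with
  min(1, ρ·f_g) afterwards. ρ = 1 gives independence; P(no mutated
  gene) = Π(1 − f_g) for every ρ, so carrier prevalence and oligogenic
  fraction are separately tunable. The coupling multiplier is an
  invention of this package — the underlying studies document the
  oligogenicity phenomenon, not a generative mechanism.
* **Defaults = study conditions.** Group sizes 61/55/72/405; male
  fraction 2/3 in case groups, 1/2 elsewhere; per-gene carrier
  frequencies proportional to the case gene spectrum (FGFR1, CHD7 and
  IGSF10 dominant; five panel genes at zero) scaled so the expected
  carrier prevalences are 51% (KS, nCHH), 6.9% (CDGP) and 17.8%
  (controls); uniform gene weights in the non-case groups. With these
  frequencies and ρ = 1, the expected CHH oligogenic fraction is already
  ≈ 15%, so independence is the default.
* **Emissions.** Recessive genes emit a homozygous variant or two
  heterozygous variants (1:1); dominant genes one het; X-linked genes a
  hemizygous call in males and a single het in females. Consequences are
  PTV (stop gain / frameshift, 1:1) with probability `fraction_ptv`
  (default 0.29, the case PTV share), else missense. Causal variants
  draw their reference MAF from the rare (< 1%) part of the spectrum —
  by definition a classified mutation is rare, so truth labels must be
  recoverable; benign background variants (Poisson, 0.5 per proband)
  draw from the full spectrum (point mass 0.5 at zero / private, else
  Beta(0.5, 3) scaled below 2.5%) and exercise the rarity and
  consequence filters on both sides of the 1% threshold. GQ ~
  N(90, 8²) clipped to [0, 99].
* **Predictor noise.** Causal missense variants receive `damaging`
  verdicts per predictor with probability `predictor_damaging_rate`
  (default 1); background variants with `benign_damaging_rate`
  (default 0 in the study configuration, so the expected
  classified-carrier prevalence equals the configured per-gene rates —
  the printed prevalences being rates of classified mutations). Setting
  these rates away from their defaults makes the classifier miss causal
  missense or call false positives, by design.
* **Not emulated:** linkage/haplotype structure, within-gene variant
  recurrence, splice-site windows for simulated variants (the splice
  path is validated by unit tests with explicit contexts), relatedness,
  population stratification. Passing recovery tests therefore show the
  pipeline is faithful to its own rules on data with this structure —
  not that the rules are complete for real exomes.

## Validation experiments

* **Oracle agreement** — the log-gamma Fisher implementation matches a
  rational-arithmetic full-enumeration oracle (and `scipy`'s
  implementation) on randomly drawn tables.
* **Parameter recovery** — 200 noiseless replicate cohorts (n = 116,
  f = 0.1, 25 genes, ρ = 1): per-gene 95% Clopper–Pearson carrier
  intervals pooled over (replicate, gene) cells cover the generating
  frequency (Clopper–Pearson guarantees ≥ 95%; ≥ 90% asserted), and
  classification reproduces the truth labels exactly.
* **Null calibration** — 1,000 contrasts of two groups (n = 116 each)
  generated with identical frequencies: the carrier-test rejection rate
  at α = 0.05 stays within 3 Monte-Carlo SDs of nominal (the exact test
  is conservative, so it sits below).

Problem sizes (200 replicates, 1,000 contrasts, 5-gene null panels) are
the package's chosen desk-scale defaults; all are configurable.

## Numerical and degenerate-input conventions

Coordinates are 1-based VCF-style; variant keys `chrom:pos:ref:alt`.
Multi-allelic records decompose into one entry per alternate allele.
Unknown consequence terms are recorded as `other` with a warning;
malformed genotype rows are skipped and counted. An empty mutation set
makes the private fraction undefined (error), as do zero-total burden
tables. Reference lookups for absent keys return zero alternate alleles
with the population's default alleles inspected (the mean over that
population's rows). Report percentages are rounded half-up at the
displayed precision and always accompanied by raw counts.

## Known limitations

The compound-heterozygote presumption overcalls biallelic states when
two hets are in cis; the in-vitro loss-of-function list is user-supplied
and applied as given; the shipped splice PWM is a baseline, not a
maximum-entropy model; the generator's variant identifiers are unique by
construction, so recurrent-allele sharing between probands is not
simulated; and the pipeline consumes annotations — it does not compute
them.
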