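# Methods

## The question and the statistic

Given per-species genome scans for local adaptation — an F_ST-outlier test
for directional selection and environmental association analyses (EAA)
against a set of topoclimatic factors — we ask whether the *same*
orthologous genes carry adaptation signatures in several species more often
than chance allows. The unit of comparison is the one-to-one ortholog key:
each species contributes a background list of functionally annotated genes
(its *universe*), and, per analysis, a candidate subset (genes containing at
least one significant SNP).

The test statistic is the cardinality of the cross-species intersection of
candidate sets. Its null distribution is built by resampling: in each of
`n_iter` iterations (10,000 by default), draw — independently for every
species — a uniform without-replacement subset of that species' universe
with size equal to the species' observed candidate count, and record the
intersection size. Then

* empirical p = #{null ≥ observed} / n_iter. The ≥ convention (and no
  +1/(n+1) pseudo-count) is fixed by the worked arithmetic this pipeline
  reproduces (16 of 10,000 exceedances reported as p = .002).
* over-representation ratio (OR) = 100·(observed/null mean − 1), a relative
  excess, not an effect size of a test.

When all cross-species sharing lies in the core shared by every species and
the remaining genes are species-private, the null mean has the closed form
`S·∏(n_i/N_i)` (each core gene enters species *i*'s draw with probability
n_i/N_i, independently across species). This closed form, and an exact
mixture-of-hypergeometrics distribution for the two-species case, serve as
oracles for the Monte-Carlo path in the tests; the resampling remains the
primary method because it extends to any species subset and to arbitrary
overlap structure.

The resampling depends only on set *sizes* plus the observed overlap, so
the published full-scale statistics can be recomputed exactly from printed
counts (universes 15,909/16,088/16,047; core 12,485; per-analysis candidate
counts). `convergescan.alpine` bundles those counts; when real candidate
*sets* are available the observed overlap is computed from them instead.

NS enrichment uses the same logic one level down: draw the number of shared
candidate genes from the shared background (12,485 genes, of which 8,681
contain nonsynonymous SNPs in all species) and count draws hitting the NS
set. The draw follows the exact hypergeometric law of that procedure.
Caveat: with only printed counts, the background is necessarily the
size-only null; at least two published per-analysis p-values (outliers,
aspect) are not recoverable under it, so they are reported as computed, not
asserted.

## Significance calling

**Outlier scan.** Upstream Bayesian F-model fits supply a posterior
probability of selection and the sign of the locus effect α per SNP.
q-values are rebuilt from posterior error probabilities (PEP = 1 −
posterior): ranking loci by PEP, q at rank *i* is the mean of the *i*
smallest PEPs (the Bayesian FDR of calling the top *i* loci); ties are
broken by input order. Directional outliers are loci with q < 0.05
(strict) *and* α > 0; negative-α loci (balancing-selection candidates) are
excluded.

**EAA.** Latent-factor association fits supply per-factor z-scores. These
are recalibrated with a genomic inflation factor λ = median(z²)/F⁻¹_χ²₁(½)
(the χ²(1) median, ≈0.4549); adjusted p = upper χ²(1) tail of z²/λ. λ is
anchored at the median for robustness to the (sparse) true signal.
q-values use Benjamini–Hochberg, by default rescaled by Storey's π₀
estimated at the single point λ = 0.5, π₀ = min(1, #{p > ½}/(n/2)) — a
deliberate simplification of the smoothed estimator, adequate at these
scales. Associations are significant at q ≤ 0.001 (inclusive). The strict
vs inclusive boundary conventions mirror the operators of the protocol
being implemented.

**Structure screen.** Pearson correlation of the first two PCs of the
population × SNP allele-frequency matrix with each factor, two-sided p from
t = r√(n−2)/√(1−r²) on n−2 df (the standard convention; a screen, not a
correction).

## Variant filtering

Two rounds with inclusive thresholds. `highconf`: qual ≥ 30, total
coverage in [20, species max], ≥ 6 alternative alleles across pools, any
variant type. `final`: biallelic SNPs only, qual ≥ 30, coverage bounds as
above, mean across-population called alternative frequency ≥ 1%, and
|called − count-based frequency| ≤ 0.2 *in every population* (the
per-population reading of the consistency rule, chosen because pooled means
could mask single-population caller artefacts). The "≥ 1%" rule is applied
to the across-population mean called frequency. Species maxima default to
120×/180×/160× for the three study species. Rejections are attributed to
the first failing rule in the fixed order qual → biallelic → min_cov →
max_cov → alt_count/alt_freq → freq_tol, making reports deterministic;
conservation (passed + rejected = input), idempotence and threshold
monotonicity are property-tested.

## Gene assignment and effect triage

A SNP belongs to every gene whose span contains it (1-based closed
intervals; spans include UTRs and introns — candidacy is gene-level, not
CDS-level). Overlapping genes each receive the SNP. Coding effect is the
three-way triage the downstream statistics need: noncoding if outside all
CDS segments; otherwise the affected codon is translated before and after
the substitution (strand-aware, alleles complemented for minus-strand
genes) and the SNP is nonsynonymous iff the amino acid changes (stop
gain/loss counts as a change). A property test checks agreement with a
brute-force oracle that translates the entire CDS.

A gene is a *top candidate* when, in every species, it carries at least one
nonsynonymous SNP significant under the same single analysis (one factor,
or the outlier scan). The overlap table separates two NS notions: genes
containing any NS SNP in all species (`shared_with_ns`) versus genes whose
NS SNP is itself significant per analysis (`shared_with_flagged_ns`).

## GO enrichment

Direct annotations are closed under is_a ancestry (true-path rule) before
testing. Each term whose propagated background count lies within
[5, 999] gets a one-sided Fisher's exact p from the candidate × term 2×2
table; Benjamini–Hochberg q; enrichment at q < 1%. Classic per-term Fisher
is used deliberately; decorrelating hierarchical variants (elim/weight)
change term rankings in ways that are algorithm-specific and are not
replicated. Term-size bounds count propagated annotations.

## The synthetic generator

The generator emulates the statistical structure the pipeline consumes, not
the biology that produced it:

* **Universes.** Per-species gene lists with an exactly configured
  all-species core, optional exactly-pairwise extras, and species-private
  remainders; IDs are TAIR-style locus strings so annotation-keyed joins
  are exercised. Defaults are the study conditions: sizes
  15,909/16,088/16,047, core 12,485.
* **Gene models.** Two-exon genes (150 nt CDS, 100 nt intron, 60 nt UTRs),
  50 per scaffold, random strand. CDS bodies are drawn from
  fourfold-degenerate codon families, which guarantees every codon has a
  synonymous third-position site and no internal stops.
* **SNPs.** Each gene gets 1 + Poisson(mean − 1) SNPs (a candidate gene
  must be able to contain a SNP, so zero-SNP genes are excluded by
  construction); default mean 21 per gene, matching roughly 335k genic SNPs
  per ~16k-gene species. A SNP is coding with probability 150/370 (the CDS
  share of the span). Coding SNPs are nonsynonymous with probability
  `ns_fraction` (default 0.5) and are *placed* to make the label true:
  second-codon-position substitutions (always amino-acid-changing in the
  standard code) for NS, third positions of fourfold codons for synonymous.
  The Bernoulli label and sequence-level classification therefore agree
  exactly, which turns the classifier into a free integration check.
* **Selection statistics.** Null posteriors Beta(1,20); a fraction
  `null_outlier_rate` (default 1%, matching observed outlier-SNP rates) get
  Beta(20,1) with mostly positive α. Association z-scores are standard
  normal; all SNPs in the `n_planted_convergent` planted genes (drawn from
  the shared core, identical across species) are shifted by `effect_shift`
  on the planted factor in every species.
* **Environment.** Gaussian populations × factors matrices with a target
  correlation (eigen-factor construction, so rank-deficient PSD targets
  like duplicated factors work); the default target is compound symmetry
  with r = 0.3, mimicking moderately redundant topoclimatic layers.

Randomness flows from one master seed through fixed substreams (one per
species for SNP tables, one per species for gene models, one for the
planted-gene choice), so any species' output is bit-reproducible and
independent of the order in which others are generated.

What the generator does **not** emulate: linkage disequilibrium, demography
and drift, coverage-dependent allele-frequency error, ascertainment from
real variant calling, orthology-inference error, or realistic GO topology.
Passing tests therefore demonstrate the correctness and calibration of the
*statistics* under the assumed independence structure, not robustness to
those real-data complications.

## Calibration and power checks

Because candidate genes are, under the null, exchangeable within a species,
any selection rule applied independently per species yields candidate sets
that are uniform given their sizes — exactly the resampling null. The
calibration test exploits this: 200 independent null datasets (400 genes
per species, 300-gene core, no planted signal), a fixed per-SNP selection
rule, 400-iteration nulls; the fraction of empirical p < .05 must fall in
the 99% binomial band around 5%. The power check plants 50 convergent genes
with a 6σ shift in 600-core universes and requires empirical p < .05
through the full calibration → candidate-set → resampling path.

The closed-form oracle comparison runs 50 random configurations at 3
Monte-Carlo SEs each; since ~0.14 chance exceedances are expected among 50
two-sided 3-SE checks, the test tolerates at most two and treats any 5-SE
deviation as bias.

## Numerical and scale choices

* Resampling uses one `numpy` Generator per (analysis, species-subset)
  substream; null counts are bit-identical for a fixed seed.
* Replication runs use 10,000 iterations (Monte-Carlo SE of the null mean
  ≲ 0.2% of its value at these sizes). The synthetic analysis drivers use
  a ~2,400-genes-per-species, 6-SNPs-per-gene study so the whole chain runs
  in seconds; statistical conclusions at this scale are qualitative
  (signal present/absent), which is why the replication step works from the
  published full-scale counts instead.
* Degenerate inputs are errors, not silences: empty posterior/p-value
  vectors, all-zero z-scores (λ undefined), zero-variance factors (named in
  the message), non-PSD correlation targets, infeasible universe
  configurations, coverage bounds missing a species, REF alleles
  contradicting the CDS.
* Flagged SNPs in unannotated genes are dropped from candidate sets (the
  annotation requirement is part of the candidate definition) but counted
  per species in `CandidateSetCollection.n_unannotated`.

## Known limitations

* The pairwise exact distribution (`hypergeom_pairwise`) is a small-instance
  oracle; its triple sum is not meant for full-scale universes.
* Greedy priority-order factor pruning is one deterministic realisation of
  "keep factors with |r| < 0.7"; other orders give other valid subsets.
* Replication mode places all cross-species sharing in the three-way core;
  pairwise expected overlaps at full scale would need the (unpublished)
  pairwise background sizes and are treated as inputs when needed.
* The Storey π₀ single-λ estimator is slightly conservative for very
  non-uniform p distributions; with the default q ≤ 0.001 threshold this
  has no practical effect on calls.
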