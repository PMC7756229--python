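# convergescan

Cross-species convergence analysis for landscape-genomic selection scans.

Three Alpine Brassicaceae species — *Arabis alpina*, *Arabidopsis halleri*
and *Cardamine resedifolia* — were scanned for signatures of local
adaptation with F_ST-outlier tests and environmental association analyses
(EAA) over Pool-Seq population data. `convergescan` implements everything
downstream of the per-SNP model fits: variant filtering, q-value
recalibration, SNP-to-gene mapping and coding-effect triage, per-species
candidate gene sets keyed by one-to-one orthology, and — the core — a
resampling test asking whether more orthologous genes carry adaptation
signatures in *all* species than expected by chance.

For an analysis *a* with candidate counts n_i drawn from annotated
backgrounds of size N_i, each of 10,000 iterations draws a uniform
without-replacement subset of size n_i per species and records the
cross-species intersection size. With observed overlap *o* and null counts
X₁…X_B:

- empirical p = #{X_b ≥ o} / B
- over-representation OR = 100·(o / mean(X) − 1) %
- closed-form check (core-only sharing): E[X] = S·∏(n_i/N_i)

Also included: a nonsynonymous-enrichment resample, top-candidate
extraction (genes with a significant NS SNP under the same analysis in
every species), GO Fisher enrichment with true-path propagation, and a
synthetic-data generator that reproduces the statistical structure of the
real inputs so the whole pipeline is testable without any sequencing data.

## Worked example

The published statistics depend only on printed set sizes, so they can be
recomputed directly (`convergescan.alpine` bundles the study counts):

```python
from convergescan import alpine, overlap_test

uni = alpine.build_universe()   # 15,909/16,088/16,047 genes, 12,485 shared
res = overlap_test(
    uni,
    alpine.CANDIDATE_SIZES["outlier"],   # 1,883 / 3,864 / 670 outlier genes
    alpine.SPECIES,
    observed=alpine.OBSERVED_SHARED["outlier"],   # 27 shared outlier genes
    n_iter=10000,
    seed=42,
)
print(f"null mean {res.null_mean:.2f}, OR {res.over_representation:.1f}%, "
      f"p = {res.empirical_p:.4g}")
```

```
null mean 14.78, OR 82.7%, p = 0.002
```

Read: random draws of the three species' candidate-set sizes share ~14.8
genes on average; the 27 observed shared outlier genes are an ~83% excess,
exceeded in only ~0.2% of random draws — strong evidence for convergent
adaptation signatures. The study's printed values (mean 14.8, 82.8%,
p = .002) are recovered to Monte-Carlo precision.

The numbered scripts under `analysis/` run the full pipeline on synthetic
data and the replication described above:

```bash
python analysis/01_simulate_inputs.py   # 3 species, planted convergent signal
python analysis/02_filter_variants.py
python analysis/03_calibrate_scans.py
python analysis/04_candidate_sets.py
python analysis/05_convergence_tests.py
python analysis/06_go_enrichment.py
```

Script 05 ends by printing, for the planted precipitation factor:

```
planted factor PRECYY: 50 shared genes vs null mean 0.01 (p = 0)
```

i.e. the 50 genes planted with a convergent association signal in all three
species are recovered with an empirical p at the resolution floor, while
all unplanted analyses stay at their null expectation.

A `convergescan` CLI wraps the same library functions
(`simulate`, `filter`, `qvalues`, `env-prune`, `converge`, `go`); see
`convergescan --help`.

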