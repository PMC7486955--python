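# phylodelta

Diagnostics for missing-data bias in supermatrix phylogenomics.

Phylogenomic studies that mix DNA from historical museum specimens with
modern tissue samples inherit a structural asymmetry: degraded specimens
yield shorter loci, lower read depth, and far more missing characters —
concentrated, in sequence-capture (UCE) data, at exactly the variable
flanking sites that carry the phylogenetic signal. The symptom is a tree in
which samples cluster by *specimen type* rather than by ancestry.

`phylodelta` implements the two-topology log-likelihood outlier framework
for localising that bias. Given topologies `T1` (estimated with
low-coverage characters retained) and `T2` (estimated after stringent
depth filtering), each alignment site is scored as

    Δ s-lk(i) = ln L(site i | T1) − ln L(site i | T2)

after independent branch-length re-optimisation on a shared evaluation
alignment under its locus partition. Sites are binned at fixed thresholds
(>20, >10, >2, <−2, <−10, <−20), per-locus sums give `Δ l-lk`, and the bins
drive repair experiments: masking outlier sites, excluding outlier loci,
trimming by data completeness in 10% steps, and starving selected samples
of their parsimony-informative sites. Tree sets are compared by
Robinson–Foulds distances with classical MDS, and sample-type clustering is
quantified as the Fitch parsimony score of the modern/historical character.

Everything runs against a synthetic UCE-study generator (Poisson read
depth by sample type, flank truncation for historical samples, paired
Low-Coverage/Filtered outputs with a known true tree), so the entire
pipeline is testable at desk scale with no external data. The likelihood
engine (pruning over column patterns, JC69/HKY85/GTR ± Γ₄, partitioned
rate multipliers, Gauss–Seidel branch optimisation, NJ+NNI search,
Felsenstein bootstrap) is part of the package.

Intended users: systematists and methods developers who want to stress-test
filtering schemes for museum-genomics datasets, or who need a transparent,
fully scriptable implementation of site/locus likelihood outlier analysis.

## Worked example

Simulate a biased paired study (18 taxa, a 16-taxon rapid radiation with
half its members historical; historical samples keep only the central 40%
of each locus at mean depth 3×, moderns are effectively complete at 30×)
and run the full Low-Coverage vs Filtered comparison:

```python
from phylodelta import StudyConfig, generate_paired_study
from phylodelta.pipeline import run_full_comparison, AnalysisConfig

bundle = generate_paired_study(StudyConfig(seed=7))
report = run_full_comparison(bundle, AnalysisConfig(seed=7))

print("RF(T1, T2):", report.rf_t1_t2)
print("type scores:", report.type_scores)
print(report.bin_summary.to_string(index=False))
```

which prints

```
RF(T1, T2): 30
type scores: {'low_coverage': 6, 'filtered': 7, 'masked_>2': 6}
 bin  n_sites  mean_missing_modern  mean_missing_historical  historical_modern_ratio
 >20        2                  0.0                    0.000                      NaN
 >10       15                  0.0                    1.000                      inf
  >2      100                  0.0                    5.000                      inf
 <-2        2                  0.0                    0.125                      inf
<-10        0                  NaN                      NaN                      NaN
<-20        0                  NaN                      NaN                      NaN
```

Reading this: the two filtering regimes give maximally different trees for
these 18 taxa (RF 30 = 2(n−3)), 100 of ~16,000 sites carry a per-site
log-likelihood advantage of more than 2 units for the Low-Coverage
topology, and at those sites historical samples average 5 missing
characters each while modern samples have none (an infinite
historical/modern ratio — the asymmetry signature). The Fitch type scores
(lower = stronger sample-type clustering; reciprocal monophyly would be 1)
show both trees moderately interleaved here. `report.site_table`,
`report.masked_trees` and `write_comparison_report(report, "out/")` expose
the full per-site table, the re-estimated masked trees and the TSV/newick
outputs.

The same workflow is scriptable from the shell:

```bash
phylodelta --seed 7 --out-dir study simulate
phylodelta --out-dir lc tree study/low_coverage.fasta study/low_coverage.partitions
phylodelta --out-dir f  tree study/filtered.fasta     study/filtered.partitions
phylodelta --out-dir out sitelik study/low_coverage.fasta \
    study/low_coverage.partitions lc/ml.nwk f/ml.nwk
phylodelta --out-dir out outliers out/site_deltas.tsv
```

## Layout

| module | contents |
|---|---|
| `phylodelta.alignment` | alignment model, FASTA/partition I/O, filters, PIS statistics, trimming, masking |
| `phylodelta.models` | JC69/HKY85/GTR, discrete-Γ rates, partitioned models |
| `phylodelta.likelihood` | pruning engine, branch optimisation, BIC model fitting |
| `phylodelta.inference` | JC distances, neighbour joining, NNI search, bootstrap |
| `phylodelta.outliers` | Δ s-lk / Δ l-lk tables, bins, masking/exclusion, subclade workflow |
| `phylodelta.treecmp` | Robinson–Foulds, classical MDS, type-clustering score |
| `phylodelta.simulate` | trees, UCE-like loci, observation model, paired studies |
| `phylodelta.predictive` | MLP prediction of Δ l-lk from locus statistics |
| `phylodelta.pipeline` | sweep / comparison / ablation experiments, report writers |
| `phylodelta.experiments` | canned replication experiments used by the acceptance script |
| `phylodelta.cli` | `phylodelta` command-line interface |
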