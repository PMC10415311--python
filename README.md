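# mitonet

Brain-wide mitochondrial phenotyping and network analysis: from raw assay
readouts (enzyme activities, qPCR Ct triplicates) to QC'd mitochondrial
features and the mitochondrial health index (MHI), behavioral composite
scores, mitochondrial connectivity matrices, Mapper-based stress-response
topology with a participation-coefficient statistic, multi-slice community
detection of mitochondria-based brain networks, cross-modal permutation
validation, network-level mito-behavior correlation, and transcriptional
mitotype/pathway scoring. A synthetic cohort generator with planted
network structure makes every stage testable without external data.

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which checks the worked
examples, closed forms, oracle equivalences (exhaustive brute-force
multi-slice quality, reference Mapper), planted-structure recovery rates,
and permutation-null calibrations. One test is conditional: it runs only if
a deposited per-animal feature table is supplied via the
`MITONET_SOURCE_DATA` environment variable (cohort-schema CSV).

## Package layout

| module | purpose |
| --- | --- |
| `mitonet.synthetic` | cohort / modality-matrix / qPCR-plate generators with planted 3-community structure |
| `mitonet.assays` | specific activities, plate normalization, mtDNAcn (2^dCt x 2) with triplicate QC, mtDNA density linearization, MHI, behavioral z-score composites, Hedges g |
| `mitonet.connectivity` | (site x feature) and per-feature area correlation matrices, nodal degree, within/between-area permutation test |
| `mitonet.mapper` | delta matrices, 2-D neighborhood-embedding filter, overlapping-bin Mapper graphs, participation coefficient, phase-randomized surrogate null |
| `mitonet.multislice` | multi-slice modularity (categorical interslice coupling), greedy optimization, module allegiance, iterative consensus communities |
| `mitonet.crossmodal` | partition alignment (area merging), strength fraction, modularity Q, size-preserving label permutation test |
| `mitonet.behavior_assoc` | Spearman mito-behavior panels with BH-FDR, Gaussian/t distribution tests, network-average behavior correlation, binomial direction test |
| `mitonet.mitotype` | network fold-change gene lists, pathway scores (mean 100 / SD 10 transform), pathway ranking, mitotype ratios, Ward clustering + PCA |
| `mitonet.io`, `mitonet.pipeline`, `mitonet.cli` | file formats, end-to-end orchestration, CLI |

## CLI

```bash
mitonet simulate --n-per-group 7 --seed 0 --out cohort.csv --behavior-out behaviors.csv
mitonet connect --cohort cohort.csv --out-dir results
mitonet multislice --cohort cohort.csv --omega 0.1 --n-runs 200 --out partition.csv
mitonet mapper --cohort cohort.csv --group CSDS --n-bins 64 --overlap 0.7
mitonet crossmodal --matrix coexpression.tsv --partition partition.csv --metric SF
mitonet behavior --cohort cohort.csv --behaviors behaviors.csv --fdr-q 0.01
mitonet mitotype --expression expr.tsv --gene-pathways g2p.tsv --partition partition.csv
mitonet run-all --seed 0 --out results
```

Default permutation/run counts are reduced for interactive use
(n_perm=2000, n_runs=200, n_null=200); `PipelineConfig(full_scale=True)`
switches to the full-scale counts (10,000 / 1,000 / 1,000).

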