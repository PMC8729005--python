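# pairpath

Path-level interpretation of Gaussian graphical models (GGMs).

The marginal Pearson correlation between two nodes of a GGM decomposes
*exactly* into signed, determinant-weighted contributions of the simple
network paths connecting them. `pairpath` computes this decomposition and
the **pair-path subscore (PPS)** — the fraction of a pair's marginal
association attributable to each path — together with:

- exact conversions between precision, partial-correlation, and marginal
  correlation matrices (`pairpath.ggm`);
- support-graph construction and bounded simple-path enumeration
  (`pairpath.paths`);
- the decomposition, subscores, and max-subscore queries with a
  path-length cutoff `K` (`pairpath.pps`);
- GGM estimation from data by inverse Pearson correlation or graphical
  lasso with cross-validated penalty, plus covariate residualization
  (`pairpath.estimation`);
- a seeded random-model generator, Gaussian sampler, and the two accuracy
  experiments (max-path identification success rate; sensitivity of the
  truncated subscore to `K`), plus the Erdős–Rényi expected-path-length
  helper for choosing `K` (`pairpath.simulate`);
- hypothesis-generation workflows: all-pairs max-PPS scans, two-condition
  difference ranking, per-node averages, edge-class summaries, and
  percentile bootstrap confidence intervals (`pairpath.workflows`).

## Python quick start

```python
import pairpath as pp

P = pp.PartialCorrMatrix(("a", "b", "c"),
                         [[1, 0.3, 0.4], [0.3, 1, 0.2], [0.4, 0.2, 1]])
table = pp.pps(P, "a", "b", k=2)
print(table.paths, table.scores)      # (('a','b'), ('a','c','b'))  (0.789, 0.211)
print(table.decomposition.reconstructed_correlation)  # == marginal corr 0.4232

ggm = pp.estimate_glasso(my_dataframe, "cv", seed=0)   # samples x features
scan = pp.max_pps_scan(ggm, k=5)
```

## Command line

```bash
pairpath simulate --nodes 10 --seed 17 --n 1000 --output sim/
pairpath estimate --data sim/samples.csv --estimator glasso --output est/
pairpath pps      --matrix est/partial_correlations.csv --pair x03 x09 --k 4 --output out/
pairpath scan     --matrix est/partial_correlations.csv --k 5 --output scan_a/
pairpath compare  scan_a/scan.tsv scan_b/scan.tsv --output diff/
pairpath bootstrap --data sim/samples.csv --pair x03 x05 --k 4 \
                   --boot-reps 1000 --seed 1 --output boot/
```

Every command writes a `metadata.json` echoing the configuration and seed
so runs can be reproduced exactly. Inputs are plain CSV (labeled square
matrix, or samples × features with a header row); outputs are TSV, JSON,
and GraphML.

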