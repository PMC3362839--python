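# aflphylo

Phylogenetics toolkit for AFLP-style dominant markers (binary band
presence/absence data), built around four stages:

1. **Scoring** (`aflphylo.scoring`) — convert peak-height tables into binary
   phenotype calls. Thresholds for locus retention and phenotype calling
   (absolute or relative to the locus mean) are optimised on a grid against
   the replicate-based mismatch error rate; loci are reduced to "unique
   loci" (polymorphic, duplicate columns collapsed).
2. **Distance trees** (`aflphylo.distance`, `aflphylo.nj`) — shared-band
   similarity F = 2·n_xy/(n_x+n_y) with the d = 1−F transform (−ln F
   available), Saitou–Nei neighbour joining with deterministic tie-breaks,
   and bootstrap support from locus (column) resampling.
3. **Hybrid detection** (`aflphylo.homoplasy`) — the leave-one-species-out
   homoplasy excess test: a hybrid taxon carries a mosaic of parental
   characters, depressing bootstrap support of clades containing its
   parents; removing it restores that support. One species is removed at a
   time, support deltas per node are recorded against the full-data
   baseline, and outlier increases (Tukey or z-score fence plus a
   minimum-increase floor) flag putative hybrids.
4. **Likelihood model comparison** (`aflphylo.likelihood`) — reversible
   two-state (restriction-site style) model with Felsenstein pruning,
   optional `noabsencesites` ascertainment conditioning (the all-absent
   pattern is unobservable), branch-length optimisation on fixed
   topologies, Shimodaira–Hasegawa tests with RELL resampling, and
   harmonic-mean marginal likelihoods feeding 2·ln Bayes-factor
   comparisons (>10 = strong evidence).

A synthetic data generator (`aflphylo.simulate`) provides ground-truth test
harnesses: pure-birth species trees, two-state characters evolved down the
tree with within-species polymorphism, plantable hybrid species built as
per-locus mosaics of two parental consensus profiles, and noisy two-component
peak-height renderings with replicate profiles.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the slower statistical acceptance suite
(NJ consistency on 200 additive matrices, pruning vs exhaustive
enumeration, SH-test conservatism/power over 100 simulations, and a
power/size study of the homoplasy excess test over 100 simulated datasets);
the remaining files are fast unit/property tests.

## CLI

```sh
aflphylo simulate --config sim.json --seed 1 --outdir out/
aflphylo score --peaks out/peaks.tsv --min-retained-frac 0.3 --outdir out/
aflphylo tree --matrix out/scored_matrix.tsv --bootstrap 1000 --seed 1 --outdir out/
aflphylo hybridtest --matrix out/scored_matrix.tsv --boot 100 --min-delta 10 --outdir out/
aflphylo topotest --matrix out/scored_matrix.tsv \
    --topology nj out/nj_tree.nwk --topology alt alt.nwk \
    --conditioning noabsencesites --rell 1000 --outdir out/
aflphylo run --config pipeline.json --outdir out/   # chained stages + manifest
```

Formats: TSV for peak tables, matrices, support tables and delta tables
(species maps and replicate pairs as `.species.tsv` / `.pairs.tsv`
sidecars), NEXUS `datatype=standard` binary characters, Newick trees
(bootstrap support as internal node labels; display convention hides
support ≤ 50 while the TSV keeps all values), JSON for reports, ground
truth and manifests. Outputs are reproducible bit-for-bit from the master
`--seed`.

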