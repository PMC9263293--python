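# plvnet

Resting-EEG functional brain-network analysis as a tested, reusable
pipeline:

1. **synthetic** — multichannel phase-coupled EEG-like cohorts with known
   ground truth: channels oscillate around shared band components with von
   Mises phase jitter, so every pairwise phase-locking value (PLV) has a
   Bessel-function closed form; two subject groups with a plantable
   alpha-band effect on frontal/temporal channels and behavioral
   covariates (reaction time, questionnaire score) tied to the latent
   network.
2. **preprocess** — zero-phase Butterworth band decomposition
   (delta/theta/alpha/beta) of the continuous record, then random
   non-overlapping epoch segmentation; 30-channel 10–20 montage with a
   five-zone lobe partition.
3. **connectivity** — instantaneous phase via the analytic signal and
   epoch-averaged PLV matrices per subject and band.
4. **network** — sparsity thresholding (K strongest edges, K = round(s ·
   N(N−1)/2), nested across the 12–40% grid) and binary graph metrics:
   characteristic path length, clustering coefficient, global and local
   efficiency, nodal degree with lobe aggregation.
5. **stats** — two-sided permutation tests of group mean differences
   (range-level, per-threshold with Benjamini–Hochberg adjustment, and
   nodal), Pearson RT–metric correlations within group, pooled-variance
   t-test and chi-square demographics.
6. **pipeline / CLI** — configuration-driven orchestration with a
   reproducible JSON + Markdown report.

Recordings are read/written as EDF or delimited text matrices; all other
artifacts are tidy TSV/JSON.

## CLI

End-to-end demo (synthetic cohort, alpha + beta bands, default 29-value
sparsity grid):

```sh
plvnet run --out out/demo --seed 1 --n-per-group 10 --duration 60
```

Stages can also be run separately, each consuming the previous stage's
files:

```sh
plvnet simulate     --out out/sim --seed 1 --n-per-group 4 --duration 30
plvnet preprocess   --in out/sim --out out/work --bands alpha --seed 1
plvnet connectivity --in out/work/epochs --out out/work
plvnet network      --in out/work/plv --cohort out/sim/cohort.tsv --out out/work
plvnet stats        --metrics out/work/metrics_global.tsv \
                    --nodal out/work/metrics_nodal.tsv \
                    --cohort out/sim/cohort.tsv --out out/work --seed 1
```

Options can come from a `key = value` config file (`--config run.cfg`);
explicit flags override file values.

## Notes

- `tests/test_acceptance.py` holds one test per acceptance criterion;
  the two multi-minute simulation checks (type-I error and power of the
  full simulate→estimate→test chain) are marked `slow`.
- Determinism: one master seed drives cohort simulation, epoch placement
  and permutation draws; identical configs produce byte-identical output
  tables.
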