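# vfarch

Archetypal decomposition and cross-modality pattern concordance for
perimetric visual fields.

`vfarch` implements a pipeline for comparing visual-field loss patterns
measured with two perimetric modalities — standard automated perimetry with a
size III stimulus (`SAP_III`) and size modulation perimetry (`SMP`) — on the
shared 42-location analysis subset of the 24-2 test grid:

1. **Grids and fields** (`vfarch.grids`, `vfarch.fields`): canonical 24-2
   (54 locations), SMP (44) and common analysis (42) grids; reference-eye
   orientation handling (left eyes mirrored on ingest); a long-format CSV
   dialect.
2. **Preprocessing** (`vfarch.preprocess`): censoring of size III
   sensitivities below 20 dB, same-day replicate averaging, linear age
   standardization to 45 years, conversion to total-deviation (TD) maps
   against a normative reference, baseline-subtracted change maps, and
   assembly of absolute (AVFA) and change (VFCA) analysis matrices.
3. **Archetypal analysis** (`vfarch.aa`): from-scratch archetypal analysis
   minimizing `||X - A B X||²` over row-stochastic A and B via alternating
   monotone accelerated projected-gradient updates, with furthest-sum
   restarts, RSS-versus-k curves (k = 2..20), elbow selection, simplex
   least-squares decomposition of individual fields into percentage weights,
   and relative-weight ranking of archetypes.
4. **Concordance** (`vfarch.concordance`): cosine similarity between
   archetype vectors, the full similarity matrix, dual best-match mapping in
   both directions, and threshold tallies (counts/fractions at ≥ 0.5, ≥ 0.8).
5. **Synthetic cohorts** (`vfarch.synth`): paired longitudinal SAP-III/SMP
   cohorts generated from eight named defect templates (arcuate, nasal step,
   paracentral, diffuse, temporal wedge, normal) with Dirichlet mixtures,
   lognormal severities, linear progression, damage-dependent SAP noise and
   flat SMP noise, plus a simulated healthy normative cohort with a known
   aging slope. Ground truth (weights, severities, rates) is returned for
   recovery testing.
6. **CLI** (`vfarch.cli`): `simulate`, `preprocess`, `rss-curve`, `fit`,
   `map`, `report` and the end-to-end `run`.

## CLI usage

Simulate a cohort and run the full absolute-field analysis:

```sh
vfarch simulate --out-dir out/sim --seed 1 --n-eyes 83 --visits 4
vfarch run --fields out/sim/fields.csv --normative out/sim/normative.csv \
    --analysis avfa --k 10 --seed 1 --out-dir out/avfa
```

`run` writes per-modality model JSONs, the two best-match mapping CSVs, a
`tallies.json` with threshold summaries, and `run.log`. Use
`--analysis vfca` for the change analysis, omit `--k` to pick the archetype
count from the RSS-curve elbow, and `--config cfg.yaml` to supply option
values from a file (explicit flags win). Every randomized command requires
`--seed`; outputs embed the seed and a configuration hash, and identical
invocations are byte-identical.

Stepwise equivalents: `vfarch preprocess` (field CSV → TD matrix CSVs),
`vfarch rss-curve`, `vfarch fit`, `vfarch map`, `vfarch report`.

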