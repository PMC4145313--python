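# commrer

Community-level **relative evolutionary rate (rER)** analysis for
metagenomic samples, built around phylogenetic placements of universal
marker-gene fragments on a fixed reference tree.

Given a rooted (or rootable) reference phylogeny, a taxon→phylum taxonomy,
and per-sample jplace placement files, the package computes:

- **rERs** — each placed fragment's root-to-tip branch length relative to the
  median root-to-tip length of reference taxa in the same phylum; community
  rER = median over a sample's markers; habitat rER = mean over samples.
- **Composition-matched null** — markers of a habitat are pooled and
  communities are re-simulated by phylum-stratified resampling at the size of
  the habitat's smallest sample; observed marker-rER distributions are
  compared to the simulated ones with two-sided Kolmogorov–Smirnov tests
  (BH-corrected across samples).
- **Pairwise dN/dS** (Nei–Gojobori counting with Jukes–Cantor correction)
  between aligned ortholog pairs, aggregated per sample.
- **Companion per-sample metrics** — annotation-hit filtering
  (length ≥ 100, identity ≥ 50 %, coverage ≥ 50 %, score ≥ 60), transposase
  level (HGT proxy), ACE richness, average genome size from marker-hit
  density, and OGT = 937·F − 335 from the IVYWREL proteome fraction.
- **COG enrichment** (ln odds ratio, one-tailed Fisher) and hierarchical
  clustering of samples on the four evolutionary variables
  (rER, dN/dS, transposase level, ACE).
- **Synthetic studies** — a first-class generator producing complete study
  bundles (reference tree with monophyletic phyla, jplace files with injected
  rate deviations, codon pairs evolved at a stated ω, annotation tables,
  abundance vectors) with full ground truth in `truth.json`.

## Quick start

```bash
# generate the default synthetic 6-habitat study (3 extreme, 3 normal)
commrer simulate --seed 1 --out study/

# run the full pipeline
commrer run --manifest study/manifest.tsv --tree study/reference.nwk \
    --taxonomy study/taxonomy.tsv --seed 1 --out results/

commrer report --results results/
```

Individual stages are available as subcommands (`rer`, `null-test`, `dnds`,
`metrics`, `enrich`, `cluster`); all share `--seed`, `--out` and `--config`
(YAML overriding `commrer.pipeline_cli.DEFAULT_CONFIG`). Outputs are
deterministic TSVs: identical config + seed ⇒ byte-identical results.

### Python API

```python
from commrer import tree_model, placement, rer_core

tree = tree_model.midpoint_root(tree_model.read_newick(newick_text))
medians = tree_model.phylum_reference_medians(tree, taxonomy)
pset = placement.read_jplace(jplace_text, tree, manifest=query_phyla)
rers = [
    rer_core.marker_rer(placement.query_tip_length(tree, rec), medians[rec.phylum])
    for rec in pset.best_per_query()
]
community = rer_core.community_rer(rers)
```

## Notes on conventions

- **rER formula**: `(L_query − phylum_median) / phylum_median` by default
  (scale-invariant); an absolute-difference variant is available via
  `rer_formula: absolute`.
- **jplace dialects**: `distal_length` is read as the offset from the
  proximal (root-facing) node by default; set `offset_from: distal` for
  producers that measure from the distal node.
- **Multi-candidate placements**: the maximum like-weight-ratio record is
  used (ties to the smaller edge number); a weight-averaged alternative is
  provided for sensitivity analysis.
- **AGS**: `marker_bp_per_genome / ((Σ hits · read_length) / total_bp)` with
  a configurable calibration constant (default 15 000 bp — the approximate
  summed length of the 31 single-copy markers). This estimator is a
  reconstruction from the published symbol definitions.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(midpoint rooting vs brute force, rER/ω/effect parameter recovery,
null-model calibration and power, Fisher p vs exhaustive hypergeometric
sums, end-to-end extreme/normal separation, byte-level determinism).

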