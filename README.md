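# splicescreen

Analysis toolkit for sequencing-based pooled splicing screens. A screen
queries thousands of arrayed mutant strains (384-well plates, biological
duplicates) for changes in the splicing efficiency of targeted introns, read
out as dual-barcoded amplicon sequencing of spliced and unspliced isoforms.

The package covers the full path from reads (or count tables) to hit calls:

- **`splicescreen.simdata`** — synthetic screens: beta-binomial count tables
  with log-normal per-sample depths, plate effects and spiked true effects;
  read-level FASTQ generation with plate barcodes and well index pairs; known
  mixing-series samples; full ground truth for recovery tests.
- **`splicescreen.readproc`** — demultiplexing (plate-barcode prefix +
  well index pair, configurable mismatch tolerance) and junction-spanning
  k-mer classification of reads into spliced / unspliced / ambiguous.
- **`splicescreen.sicore`** — splice index SI = unspliced/spliced per sample,
  plate-median normalization (relative SI), replicate-concordance and
  read-depth QC filters, dataset summaries (median SI, IQR, replicate R²).
- **`splicescreen.nullmodel`** — depth-dependent empirical null: 20
  equal-size read-depth bins, natural cubic splines through the per-bin mean
  and SD of log2 relative SI, Z-scores, two-sided p-values,
  Benjamini-Hochberg correction, ±2σ confidence intervals.
- **`splicescreen.screenstats`** — Fisher's exact overlap enrichment between
  per-target hit lists, hit unions, and one-call pipeline orchestration.

## CLI

```sh
# synthetic screen (counts + truth; add --reads for FASTQ + manifest)
splicescreen simulate --n-plates 2 --seed 1 --out-dir out/sim

# reads -> per-sample counts
splicescreen count --fastq reads.fastq --scheme scheme.tsv \
    --layout layout.tsv --out counts.tsv

# counts -> splice indices, QC, summaries
splicescreen si --counts counts.tsv --out out/si

# measurements -> null model + calls
splicescreen call --measurements out/si/measurements.tsv --bins 20 --alpha 0.05 --out out/calls

# everything at once (simulate or analyze mode)
splicescreen run --mode simulate --seed 1 --out-dir out/run
splicescreen run --mode analyze --counts counts.tsv --out-dir out/run
```

`run` writes all intermediate tables (TSV), a JSON dump of the fitted null
model knots, a machine-readable summary, and a Fig-2-style scatter export
(log10 reads, log2 relative SI, significance) as data.

## Library quick start

```python
from splicescreen import simdata, screenstats

cfg = simdata.SimulationConfig(n_plates=8, spiked_fraction=0.02, seed=1)
result = screenstats.run_screen_pipeline(config=cfg, out_dir="out")
print(result["summary"])
```

## Tests

```sh
python -m pytest tests/
```

The suite includes brute-force oracles (BH step-up, hypergeometric
enumeration, containment-alignment read classification) and statistical
acceptance checks (p-value calibration, FDR/power, lossless read round
trips). Two tests in `tests/test_acceptance.py` require the original
study's raw supplementary count table at
`data/supplementary_table_s1.tsv` (TSV: strain_id, target, replicate,
plate, well, spliced, unspliced); without it they fail with an explanatory
message — they are replication checks against external data that cannot be
redistributed here.

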