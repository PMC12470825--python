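# glyzip

Context-aware analysis of GXXXG (glycine-zipper) motif landscapes in protein
sequences: overlap-aware motif scanning, transmembrane-coverage
classification across thresholds, TM-only / shared / non-TM partitioning,
heavy-tailed distribution fitting (Zipf regression, discrete power-law MLE
with KS-based x_min selection, power-law-vs-lognormal likelihood-ratio
tests), Shannon entropy and KL / Jensen–Shannon divergence profiling, and
positional amino-acid enrichment with Fisher's exact tests under
Benjamini–Hochberg FDR control.

Inputs are plain files: FASTA sequences plus either locally stored UniProt
entry XML (feature type "transmembrane region") or a simple TM-feature TSV
sidecar. A built-in synthetic-proteome generator plants motifs, TM segments,
context-dependent composition biases, heavy-tailed motif-type frequencies,
and redundancy clusters with a ground-truth manifest, so the entire pipeline
is testable offline.

## CLI

Seven file-to-file subcommands that compose via the shell exactly as the
internal pipeline composes them:

```sh
glyzip simulate --seed 7 --out sim/                    # synthetic proteome + manifest
glyzip dedupe   --fasta sim/proteome.fasta \
                --tm-features sim/tm_features.tsv \
                --metadata sim/proteins.tsv --out dd/  # redundancy removal
glyzip extract  --fasta dd/nonredundant.fasta \
                --tm-features dd/nonredundant_tm_features.tsv \
                --out instances.tsv                    # motif scan + TM coverage
glyzip classify --instances instances.tsv --out out/   # threshold partitions + sweep
glyzip stats    --instances instances.tsv --seed 7 --out out/   # fits, entropy, divergences
glyzip compose  --instances instances.tsv --out out/   # composition + enrichment
glyzip report   --dir out/                             # assemble summary.tsv
```

`glyzip simulate --config cfg.yaml` accepts a YAML simulation config
(fields of `glyzip.simulate.SimConfig`). The full pipeline is also available
programmatically:

```python
from glyzip.pipeline import PipelineConfig, run_pipeline
from glyzip.simulate import SimConfig

run_pipeline(PipelineConfig(outdir="out", seed=7, sim=SimConfig(seed=7)))
```

All randomness flows from the single config seed; outputs are
byte-identical across reruns.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (scanner/coverage
oracle equivalence, partition algebra, entropy and divergence identities,
Zipf and power-law recovery, LRT sign tests, Fisher enumeration oracle,
redundancy collapse, and the end-to-end qualitative signature).

## Package layout

| module                | contents |
| --------------------- | -------- |
| `glyzip.core`         | domain types (`ProteinRecord`, `TMFeature`, `MotifInstance`, `MotifCountTable`) and FASTA / UniProt-XML / TSV readers and writers |
| `glyzip.simulate`     | synthetic proteome generator with ground-truth manifest |
| `glyzip.extract`      | overlap-aware GXXXG scanner and TM-coverage engine |
| `glyzip.redundancy`   | pairwise global-alignment identity, organism-scoped redundancy clustering, dedupe |
| `glyzip.classify`     | threshold classification, unique-motif partitioning, sweep metrics, chi-square |
| `glyzip.diststats`    | rank–frequency, Zipf regression, discrete power-law MLE, Vuong LRT vs lognormal, entropy with bootstrap CI, KL/JSD |
| `glyzip.composition`  | X1/X2/X3 composition profiles, log2 enrichment, Fisher + BH FDR |
| `glyzip.pipeline`     | file-to-file stages and `run_pipeline` |
| `glyzip.cli`          | click entry points |
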