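# zebscreen

Analysis toolkit for nominating ZEB1/NuRD co-repressor target genes from
three complementary screens:

* **interactome** — SAINT-style posterior scoring of BioID (proximity
  labeling) spectral counts against a FlagBirA*-only control, and the
  high-confidence filter (max score > 0.8, > 2 unique spectra in both
  analyses, ≥ 2.5-fold counts over control).
* **screen** — pooled shRNA dropout-screen read processing: fixed-position
  spacer filtering (`CGAA` at base 18, one mismatch allowed), barcode
  demultiplexing (targeting window 23–40, non-targeting 1–18),
  counts-per-million normalization, log2 fold-change percentiles, and
  replicate collapsing.
* **rsa** — the redundant shRNA activity (RSA) hypergeometric gene statistic
  (reported as log10 p), differential essentiality between two cell-line
  arms, and intersection of the top differential fraction with the filtered
  interactor list.
* **funnel** — ChIP co-occupancy → inverse-expression → TSS-proximity
  (±250 bp) → E-box (`CACCTG`) target prioritization with a per-gene audit
  trail; ships a bundled 37-gene candidate expression table.
* **synth** — deterministic generators for all three input families
  (spectral-count tables, barcoded FASTQ read sets, peak/expression/promoter
  fixtures) with planted ground truth, so the entire pipeline is testable
  offline.
* **io / pipeline / cli** — FASTA/FASTQ/BED/TSV readers and writers, YAML
  configuration, a run manifest, and the umbrella CLI.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, one test per
criterion. Three of them fail by design in an offline checkout; see the
module docstring: two need deposited supplementary source data that is not
redistributable here, and one asserts a recovery target that is above the
pigeonhole bound of its own configuration.

## CLI

```sh
# end-to-end synthetic run
zebscreen pipeline run --seed 1 --out out/

# generate fixtures
zebscreen simulate bioid  --seed 1 --out fixtures/bioid
zebscreen simulate screen --seed 1 --out fixtures/screen
zebscreen simulate funnel --seed 1 --out fixtures/funnel

# interactome
zebscreen bioid score  --counts fixtures/bioid/bioid_counts.tsv --out scores.tsv
zebscreen bioid filter --scores scores.tsv --min-score 0.8 --min-unique 3 \
    --min-fold 2.5 --out interactors.tsv

# screen read processing
zebscreen screen demux --library fixtures/screen/library.tsv \
    --fastq arm_A_ref=fixtures/screen/arm_A_ref.fastq \
    --fastq arm_A_vitro_r1=fixtures/screen/arm_A_vitro_r1.fastq \
    --out counts.tsv
zebscreen screen normalize --counts counts.tsv --out norm.tsv
zebscreen screen fold --norm norm.tsv --reference arm_A_ref \
    --library fixtures/screen/library.tsv --out folds.tsv
zebscreen screen collapse --folds folds.tsv \
    --group arm_A:in_vitro=arm_A_vitro_r1 --out collapsed.tsv

# RSA and differential ranking
zebscreen rsa score --collapsed collapsed.tsv \
    --library fixtures/screen/library.tsv --arm arm_A:in_vitro --out rsa_a.tsv
zebscreen rsa diff --arm-a rsa_a.tsv --arm-b rsa_b.tsv --out diff.tsv
zebscreen rsa intersect --diff diff.tsv --interactors interactors.tsv \
    --top-fraction 0.15 --out hits.txt

# target funnel
zebscreen funnel --zeb1 fixtures/funnel/peaks_a.bed \
    --chd4 fixtures/funnel/peaks_b.bed --ann fixtures/funnel/annotation.tsv \
    --expr fixtures/funnel/expression.tsv \
    --promoters fixtures/funnel/promoters.fa --window 250 --out audit.tsv
```

## Layout

```
src/zebscreen/       one module per pipeline stage (+ bundled data table)
tests/               pytest suite; test_acceptance.py = acceptance criteria
scripts/acceptance.py
```
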