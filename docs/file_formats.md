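# File formats

All tabular artifacts are tab-separated with `#`-prefixed provenance
comment lines (tool version, subcommand, seed, config hash) before the
header row. Coordinates are 0-based, half-open.

## Ladder annotation (`<prefix>.annotation.tsv`)

| column | meaning |
|---|---|
| `ladder_id` | molecule identifier (FASTA record id) |
| `start`, `end` | interval on the molecule, 0-based half-open |
| `feature` | `flank_5p`, `element`, `spacer` or `flank_3p` |
| `element_id` | element identifier, `.` for non-element features |
| `copy_index` | 0-based index of this copy of the element, `.` otherwise |
| `cn` | copy number of the element, `.` otherwise |

Intervals tile each molecule without gaps or overlaps; slicing the FASTA
sequence with them reconstructs every element byte-identically (this is how
`read_ladder_set` rebuilds a design).

## Design manifest (`<prefix>.manifest.tsv`)

`ladder_id`, `element_id`, `cn`, `source_template`, `source_start`,
`source_end` — the provenance of each element's shuffled template window.

## k-mer count table (`count --out`)

`kmer` (canonical 31-mer string), `count` (non-negative integer).

## Metrics outputs (`metrics --out-prefix`)

- `<p>.profile.tsv`: `cn`, `n_kmers`, `mean`, `median`, `sd`, `cv` per unit.
- `<p>.metrics.tsv`: `slope`, `intercept`, `r_squared`, `ratio_mean`,
  `ratio_sd` of the count-vs-cn fit.
- `<p>.ratios.tsv`: `ladder`, `pair` (e.g. `2/1`), `ratio` of per-ladder
  median counts between successive units.

## Calibration (`calibrate --out`)

`cn`, `raw_median`, `calibrated_median`, `scale`, `in_range_fraction`.

## Fold-difference test (`difftest --out`, `evaluate` tests table)

`feature`, `count_a`, `count_b`, `diff`, `cn_level` (assigned unit), `sd`
(technical SD at that level), `z`, `p`, `q` (Benjamini–Hochberg),
`significant` (q ≤ α), `degenerate_sd`.

## Count matrix (input to `normalize` / `evaluate`)

`feature`, `is_ladder` (boolean), `cn` (unit for ladder rows, `.`
otherwise), then one integer column per sample. Truth tables for
`evaluate`: `feature`, `fold_change` (designed B/A ratio).

## Normalization outputs (`normalize --out-prefix`)

- `<p>.factors.tsv`: `sample`, `factor` (normalized counts = counts/factor).
- `<p>.rle.tsv`: `sample`, `rle_median`, `rle_iqr`, `n_features`,
  `n_excluded_zero_median`.
- `<p>.normalized.tsv`: `feature` plus one normalized column per sample.

## Sweep (`sweep --out`)

`variable`, `setting`, `slope`, `r_squared`, `ratio_mean`, `cv_1cn`,
`cv_2cn`, `cv_4cn`, `cv_8cn` — one row per grid setting.

## Simulation truth tables

- Diploid (`simulate diploid`): `locus`, `kind` (`locus`/`background`),
  `cn` (1 or 2), `kmer` (canonical 31-mer).
- Community (`simulate community`): `pair` (e.g. `A-B`), `species`,
  `fold_change` (designed relative-abundance ratio).

## Sequence formats

FASTA is written wrapped at 80 columns; ids are ladder ids or template
ids. Paired FASTQ uses 4-line records with `/1`/`/2` name suffixes and a
constant Q30 quality placeholder (no quality-aware logic exists
downstream). Sequence formats carry no comment lines, so their provenance
lives in the run log and companion tables.
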