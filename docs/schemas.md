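# File schemas

All tables are tab-separated UTF-8 text with a `.` decimal separator, `NA`
for absent values, and a first-line schema comment `# resistex <kind> v1`.
Write-then-read is the identity on valid data.  One hand-written example of
each file lives in `examples/data/`.

## Integrated table (`integrated-table`)

The central artifact: one row per transcript, a leading `transcript` column,
then one `<dataset>_FC` / `<dataset>_Q` column pair per dataset.

- `FC`: linear fold change, resistant over susceptible; must be > 0.
- `Q`: Benjamini–Hochberg adjusted p-value in [0, 1].
- `FC` and `Q` are absent (`NA`) together or not at all.
- Optional `<dataset>_DISCORDANT` columns (0/1) mark cells where the probe
  consensus rule failed; these are written only when at least one cell is
  discordant, and a discordant cell always has `NA` values.

Example: `examples/data/integrated.tsv`.

## Dataset metadata (`metadata`)

One row per dataset: `dataset_id`, `country`, `species` (gambiae /
coluzzii / arabiensis), `latitude`, `longitude` (decimal degrees),
`resistance_class` (high / moderate / low / susceptible), `mortality_pct`
(WHO discriminating-dose mortality, optional), `exposure` (DDT /
pyrethroid / bendiocarb / none / unknown), `kdr_frequency` (proportion,
optional), `year`, `comparator` (susceptible reference strain).

When both are present, `resistance_class` must agree with the mortality
bins: [0, 33) high, [33, 66) moderate, [66, 100) low, exactly 100
susceptible.

Example: `examples/data/metadata.tsv`.

## Probe annotation (`probe-annotation`)

`probe_id`, `transcript_ids` (comma-joined), `cross_hyb` (0/1).  A probe
must map to at least one transcript; `cross_hyb` must be 1 whenever the
targets span more than one gene.

Example: `examples/data/annotation.tsv`.

## Gene sets (`gene-sets`)

Long format: `name`, `member`; one row per (set, member) pair.

Example: `examples/data/gene_sets.tsv`.

## Probe-level DE results (`probe-results`)

`dataset_id`, `probe_id`, `fold_change` (> 0, linear), `q_value` ([0, 1]).
This is the input to probe→transcript aggregation; the `dea` command's
output adds `mean_M`, `t_mod`, `df_total` and `p_value` columns.

Example: `examples/data/probe_results.tsv`.

## Raw two-colour signals (`raw-signals`)

`array_id`, `probe_id`, `red`, `green` (positive background-corrected
intensities), `dye_swapped` (0/1; 1 when the resistant sample is in the
green channel).  All arrays of one experiment must share the probe list and
order.

Example: `examples/data/raw_signals.tsv`.

## Map output

GeoJSON FeatureCollection of Point features; each feature's properties are
`dataset_id`, `category` (`down`, `up_low`, `up_high`), `fold_change`,
`q_value`.  A TSV mirror with `latitude`/`longitude` columns is available
from the `map` command via `--tsv`.
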