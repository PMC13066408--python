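# File formats

All tabular files are UTF-8, tab-separated, with a header row.
Coordinates are 1-based inclusive (VCF/SEG convention). Booleans are
`true`/`false`; missing optional values are empty fields.

## Variant table (TSV dialect)

Columns (required unless noted):

| column | type | notes |
|---|---|---|
| patient_id | str | |
| sample_id | str | one sample = one patient timepoint |
| timepoint | int | days since diagnosis (0 = primary) |
| chrom | str | with or without `chr` prefix |
| pos | int | 1-based |
| ref, alt | str | DNA strings |
| gene | str | panel gene symbol, nonempty |
| protein_change | str | optional |
| vaf | float in [0,1] | optional if alt_reads+depth given |
| depth | int > 0 | |
| alt_reads | int | optional; when present and in conflict with `vaf` beyond 0.5/depth, the read counts win (a warning is logged) |

The reader keeps calls with `vaf >= vaf_threshold` (default 0.10, the
panel detection threshold; pass 0.01 for the sensitivity mode).

## Variant table (VCF dialect)

VCF 4.x with `AD` (allelic depths) and `DP` in FORMAT, the gene symbol
in `INFO/GENE`, and sample names encoding patient and timepoint as
`<patient_id>:<timepoint>`.

## CNV segment table (SEG-like TSV)

| column | type | notes |
|---|---|---|
| patient_id, sample_id, timepoint | as above | |
| chrom, start, end | str, int, int | 1-based inclusive |
| cn | int in 0..4 | integer copy-number class |
| loh | bool | `true` only with cn = 2 (copy-neutral LOH) |
| baf | float in [0,1] | optional; mirrored internally |
| logr | float | optional, diagnostic |
| fraction | float in [0,1] | optional explicit cell fraction; bypasses BAF inversion |

Classes: cn 0–1 = `del`, cn 2 + loh = `LOH`, cn 3–4 = `dup`.

## Clinical table

`patient_id, entity (T-ALL|T-LBL), age_group (pediatric|adult),
age_years, relapsed, time_to_event_days, event_observed,
sample_timepoints` (comma-separated ints, optional). One row per
patient; `relapsed = true` requires `event_observed = true`.

## Clone-tree JSON (`schema_version: 1`)

```json
{
 "schema_version": 1,
 "patient_id": "UPN0001",
 "timepoints": [0, 1080],
 "nodes": [
  {"node_id": "K1", "parent_id": null,
   "events": ["PHF6", "LOH_in_9p"],
   "ccf_by_timepoint": {"0": 0.98, "1080": 0.99}},
  {"node_id": "K2", "parent_id": "K1",
   "events": ["dup20"],
   "ccf_by_timepoint": {"0": 0.60, "1080": 0.07}}
 ]
}
```

Exactly one node has `parent_id: null`; parent references must be
acyclic; CCFs are subtree-inclusive fractions in [0, 1]. A node with id
`NORMAL` (empty events, CCF 1.0) appears only when the reconstruction
could not settle on a single founding clone. Writing refuses documents
that violate these invariants; `read(write(t))` is the identity.

## Simulated cohort directory

`clonetraj simulate --out DIR` writes `variants.tsv`, `segments.tsv`,
`clinical.tsv` (formats above), `truth.json` (list of per-patient truth
records: tree document, per-timepoint purity, event kinds, planted
covariate and outcome) and `manifest.json` (seed, config hash, file
list). Output is byte-identical for a fixed config; an existing
non-empty directory is refused without `--force`.
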