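# Real-data inputs (not distributed)

The acceptance tests that validate against the published record set look
for these files here; they are not shipped with the repository and must be
supplied by the user:

- `NC_022684.1.gb` — the *Arborophila brunneopectus* complete mitogenome,
  GenBank flat-file format.
- `mitogenomes_45.gb` — a multi-record GenBank flat file with the 45
  mitogenomes of the comparative analysis.
- `nd3_states.tsv` — per-species ND3 state table, tab-separated columns
  `accession  taxon  order  state` with state `WEC` or `WOC`.

When a file is missing the corresponding test fails with a message naming
it; all other tests are self-contained.
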