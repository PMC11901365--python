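# Supplementary sequence tables (not redistributable — supply locally)

Placing the following CSV files here enables the data-dependent acceptance
tests (criteria 1–3) and the corresponding `scripts/acceptance.py` targets:

- `table_s1.csv` — therapeutic reference set:
  columns `id, sequence_heavy, sequence_light`
- `table_s5.csv` — approved/discontinued set:
  columns `id, sequence_heavy, sequence_light, status`
  with `status` in `{approved, discontinued}`

Sequences are one-letter amino-acid variable-domain chains. Without these
files the related tests fail with a diagnostic and the acceptance report
omits the corresponding target keys.
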