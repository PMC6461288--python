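# Sheet/column role mapping for the supplementary-XLSX dialect.
# Keys under `columns` are the canonical long-format roles; values are the
# column headers as they appear in the spreadsheet. Edit to match a concrete
# file (or pass an equivalent dict as `layout=` to read_size_table).
sheet: 0
columns:
  sample_id: sample_id
  label: label
  chromosome: chromosome
  length_bp: length_bp
  count: count
# Used when the spreadsheet carries no label column.
default_label: unknown
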