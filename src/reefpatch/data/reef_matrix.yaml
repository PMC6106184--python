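# Default Sabellaria spinulosa reef structure matrix.
# Rows: percentage-cover bands (<10, 10-20, 20-30, >30 %).
# Columns: tube-elevation bands (<2, 2-5, 5-10, >10 cm).
# Bands are left-closed, right-open; cover 0 is handled separately as NoReef.
cover_band_edges: [0, 10, 20, 30, 100]
elevation_band_edges: [0, 2, 5, 10, .inf]
cells:
  - [NotAReef, NotAReef, NotAReef, NotAReef]
  - [NotAReef, Low,      Low,      Low]
  - [NotAReef, Low,      Medium,   Medium]
  - [NotAReef, Low,      Medium,   High]
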