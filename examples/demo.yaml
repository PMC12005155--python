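# 50-gene demo: simulate all three conditions and run every stage.
seed: 11
outdir: out/demo
simulate:
  n_genes: 50
  n_fragments: 30000
  spacing_bp: 165
  ndr_width_bp: 140
  samples: [WT, K192N, 141-305]
bins:
  short: "0:60"
  nucleosome: "142:152"
  body: "80:170"
vplot:
  anchors: [1]
  max_offset: 400
  length_range: "35:170"
profile:
  bin: short
  flank: 500
  mode: overlap
heatmap:
  bin: short
  flank: 400
shift_test:
  bin: nucleosome
  alpha: 0.05
  min_genes: 5
  stratify: length
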