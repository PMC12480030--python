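{
  "name": "CYP2C19",
  "chromosome": "10",
  "strand": "+",
  "assembly": "GRCh38-like (simplified desk-scale locus model)",
  "exons": [
    [94762681, 94762850],
    [94775100, 94775400],
    [94780500, 94780800],
    [94781300, 94781600],
    [94781800, 94782000],
    [94827700, 94827950],
    [94842300, 94842500],
    [94849600, 94849800],
    [94852700, 94852900]
  ]
}
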