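{
  "seed": 42,
  "outdir": "demo_run",
  "focal_code": "resultomonadaceae-okinawensis-mito",
  "simulate": {
    "n_genes": 15,
    "n_reference_taxa": 20,
    "substitution_prob": 0.15,
    "editing_site_rate": 0.005
  }
}
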