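# Demo run on a fully synthetic study at the default conditions:
# 132 samples, 3 sub-populations (Fst 0.15), 3 environments, 3 causal chalk
# loci, 3000 SNPs, 400-1004 nm scenes. `grainspec run --config` executes
# every stage and writes a manifest with checksums.
outdir: results/demo
seed: 1
simulate: true
sim: {}
stages:
  extract: true
  classify: true
  trait_spectra: true
  gwas: true
  segments: true
  genes: true
preprocess: none
classify_target: subpop
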