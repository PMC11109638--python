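# Demo pipeline: a lineage with an ancient shared WGD and a recent private WGD,
# plus a dated sister lineage providing the ortholog calibration point.
seed: 42
out_dir: results/demo
focal: focal
sister: sister
ancestor: outgroup
sister_divergence_mya: 98.55
simulate:
  n_chromosomes: 5
  genes_per_chromosome: 80
  codons_per_gene: 200
  rate_r: 4.29e-9
  fractionation_loss: 0.1
  ks_scatter_sigma: 0.15
  mode: ks_level
  schedule:
    - {time: 130.0, lineage: anc, kind: speciation, params: {children: [outgroup, ranun]}}
    - {time: 122.31, lineage: ranun, kind: wgd}
    - {time: 98.55, lineage: ranun, kind: speciation, params: {children: [focal, sister]}}
    - {time: 15.14, lineage: focal, kind: wgd}
synteny:
  max_gap: 25
  min_block_anchors: 5
ksdist:
  ks_min: 0.01
  ks_max: 5.0
  k_max: 3
  n_restarts: 10
  bootstrap: 30
karyotype:
  min_segment_anchors: 5
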