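genome:
  chromosomes:
    chr1: 5000000
    chr2: 5000000
  background_gc: 0.4
subregions:
  CCDS:
    n_targets: 1500
    target_length: 200
    gc: 0.5
    one_in_x: 1500
    spectrum:
      A>C: 0.03125
      A>G: 0.1875
      A>T: 0.03125
      C>A: 0.03125
      C>G: 0.03125
      C>T: 0.1875
      G>A: 0.1875
      G>C: 0.03125
      G>T: 0.03125
      T>A: 0.03125
      T>C: 0.1875
      T>G: 0.03125
    private_prob: 0.09
    fixed_prob: 0.06
    conservation:
      kind: normal
      mean: 1.5
      sd: 1.0
      value: 0.0
  refseq_vega_specific:
    n_targets: 600
    target_length: 150
    gc: 0.48
    one_in_x: 1200
    spectrum:
      A>C: 0.03571428571428571
      A>G: 0.17857142857142858
      A>T: 0.03571428571428571
      C>A: 0.03571428571428571
      C>G: 0.03571428571428571
      C>T: 0.17857142857142858
      G>A: 0.17857142857142858
      G>C: 0.03571428571428571
      G>T: 0.03571428571428571
      T>A: 0.03571428571428571
      T>C: 0.17857142857142858
      T>G: 0.03571428571428571
    private_prob: 0.1
    fixed_prob: 0.05
    conservation:
      kind: normal
      mean: 1.0
      sd: 1.0
      value: 0.0
  conserved_UTR:
    n_targets: 800
    target_length: 150
    gc: 0.3
    one_in_x: 2300
    spectrum:
      A>C: 0.041666666666666664
      A>G: 0.16666666666666666
      A>T: 0.041666666666666664
      C>A: 0.041666666666666664
      C>G: 0.041666666666666664
      C>T: 0.16666666666666666
      G>A: 0.16666666666666666
      G>C: 0.041666666666666664
      G>T: 0.041666666666666664
      T>A: 0.041666666666666664
      T>C: 0.16666666666666666
      T>G: 0.041666666666666664
    private_prob: 0.09
    fixed_prob: 0.06
    conservation:
      kind: normal
      mean: 1.2
      sd: 1.0
      value: 0.0
  nonconserved_UTR:
    n_targets: 800
    target_length: 200
    gc: 0.4
    one_in_x: 925
    spectrum:
      A>C: 0.041666666666666664
      A>G: 0.16666666666666666
      A>T: 0.041666666666666664
      C>A: 0.041666666666666664
      C>G: 0.041666666666666664
      C>T: 0.16666666666666666
      G>A: 0.16666666666666666
      G>C: 0.041666666666666664
      G>T: 0.041666666666666664
      T>A: 0.041666666666666664
      T>C: 0.16666666666666666
      T>G: 0.041666666666666664
    private_prob: 0.11
    fixed_prob: 0.05
    conservation:
      kind: normal
      mean: 0.2
      sd: 1.0
      value: 0.0
  regulome:
    n_targets: 1200
    target_length: 100
    gc: 0.7
    one_in_x: 750
    spectrum:
      A>C: 0.04807692307692307
      A>G: 0.15384615384615385
      A>T: 0.04807692307692307
      C>A: 0.04807692307692307
      C>G: 0.04807692307692307
      C>T: 0.15384615384615385
      G>A: 0.15384615384615385
      G>C: 0.04807692307692307
      G>T: 0.04807692307692307
      T>A: 0.04807692307692307
      T>C: 0.15384615384615385
      T>G: 0.04807692307692307
    private_prob: 0.12
    fixed_prob: 0.05
    conservation:
      kind: normal
      mean: 0.5
      sd: 1.0
      value: 0.0
  predicted_exons:
    n_targets: 800
    target_length: 150
    gc: 0.55
    one_in_x: 714
    spectrum:
      A>C: 0.03787878787878788
      A>G: 0.17424242424242423
      A>T: 0.03787878787878788
      C>A: 0.03787878787878788
      C>G: 0.03787878787878788
      C>T: 0.17424242424242423
      G>A: 0.17424242424242423
      G>C: 0.03787878787878788
      G>T: 0.03787878787878788
      T>A: 0.03787878787878788
      T>C: 0.17424242424242423
      T>G: 0.03787878787878788
    private_prob: 0.16
    fixed_prob: 0.04
    conservation:
      kind: mixture
      mean: 0.0
      sd: 1.0
      value: 0.0
      components:
      - weight: 0.7
        mean: 0.0
        sd: 1.0
      - weight: 0.15
        mean: 2.5
        sd: 1.0
      - weight: 0.15
        mean: -2.5
        sd: 1.0
  miRNA:
    n_targets: 200
    target_length: 100
    gc: 0.55
    one_in_x: 1500
    spectrum:
      A>C: 0.041666666666666664
      A>G: 0.16666666666666666
      A>T: 0.041666666666666664
      C>A: 0.041666666666666664
      C>G: 0.041666666666666664
      C>T: 0.16666666666666666
      G>A: 0.16666666666666666
      G>C: 0.041666666666666664
      G>T: 0.041666666666666664
      T>A: 0.041666666666666664
      T>C: 0.16666666666666666
      T>G: 0.041666666666666664
    private_prob: 0.1
    fixed_prob: 0.05
    conservation:
      kind: normal
      mean: 1.0
      sd: 1.0
      value: 0.0
  intron:
    n_targets: 300
    target_length: 2000
    gc: 0.4
    one_in_x: 850
    spectrum:
      A>C: 0.041666666666666664
      A>G: 0.16666666666666666
      A>T: 0.041666666666666664
      C>A: 0.041666666666666664
      C>G: 0.041666666666666664
      C>T: 0.16666666666666666
      G>A: 0.16666666666666666
      G>C: 0.041666666666666664
      G>T: 0.041666666666666664
      T>A: 0.041666666666666664
      T>C: 0.16666666666666666
      T>G: 0.041666666666666664
    private_prob: 0.12
    fixed_prob: 0.05
    conservation:
      kind: normal
      mean: 0.0
      sd: 1.0
      value: 0.0
depth:
  baseline_depth: 100.0
  gc_optimum: 0.5
  gc_width: 0.17
  capture_exponent: 1.5
  dispersion: null
  gc_window: 100
annotations:
  quality_mean: 80.0
  quality_sd: 20.0
  depth_mean: 100.0
  alt_fraction_a: 8.0
  alt_fraction_b: 8.0
  low_mapq_a: 1.0
  low_mapq_b: 19.0
  maf_low: 0.01
  maf_high: 0.99
seed: 0
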