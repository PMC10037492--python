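# Small end-to-end demo: a 300 kb genome with two exposure doses.
# Run:  damagemap --seed 7 --out-dir demo_out run-all --config configs/demo.yaml
seed: 7
simulate:
  genome_length: 300000
  gc: 0.41
  gc_sd: 0.05
  n_sites: 6000
  doses:
    low: 0.45
    high: 0.8
  ndna_purity: 0.9
  n_replicates: 2
  n_reads: 20000
  read_length: 50
  n_open_regions: 60
  open_region_length: 1500
  n_genes: 80
  gene_length: 1200
  open_region_survival: 0.4
  ts_survival: 0.6
bin_width: 10000
candidate_bin_widths: [2000, 5000, 10000, 20000, 50000]
epsilon: 1.0
flank: 2000
profile_bin: 25
nmf_k: 2
nmf_restarts: 20
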