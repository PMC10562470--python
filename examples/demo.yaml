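# Demo configuration: a small two-superkingdom mock community, genomes with
# the 16S embedded on random strands, noisy full-length reads, and the whole
# design -> in-silico PCR -> classification -> comparison workflow.
seed: 7
community:
  n_bacteria: 5
  n_archaea: 3
  archaeal_abundance: 0.3
  congeneric_pairs: 2
  template_len: 1500
  cons_rate: 0.01
  var_rate: 0.20
  clade_signature: 25
genomes:
  length: 4000
reads:
  n_reads: 60
  sub_rate: 0.02
  ins_rate: 0.015
  del_rate: 0.015
design:
  target_tm: 45.0
  tol_c: 6.0
  win_len: 18
  min_mean_cons: 0.96
  max_gap_frac: 0.10
  core_len: 22
  amplicon_min: 1250
  amplicon_max: 1750
classify:
  len_lo: 1250
  len_hi: 1750
  min_ref_cov: 0.60
  min_identity: 0.80
rank: genus
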