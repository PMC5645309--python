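# Reduced-size demo run: same model and caller settings as the standard
# scenario, smaller genome and library so it completes in seconds.
seed: 11
n_chrom: 2
chrom_len: 300000
n_reads: 60000
control_reads: 3000
gamma: 20.0
p_self: 0.2
p_uncut: 0.05
read_len: 75
caller:
  window: 3
  iterations: 1000
  fdr: 0.01
  fdr_prob: 0.05
smoothing_window: 9
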