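# Small demonstration run: three observers that underweight the prior in
# decisions (w_choice) more than in confidence (w_conf).
seed: 11
n_participants: 3
sessions: 2
blocks_per_session: 10
group_medians:
  w_choice: 2.17
  w_conf: 1.27
  b: 2.18
between_sd_log: 0.2
sigma: 0.1
report_noise_sd: 0.1
sampler:
  n_burn: 300
  n_steps: 500
out_dir: runs/small
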