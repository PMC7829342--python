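# Reduced demo study: 8 + 8 participants, 8 sessions, light MCMC.
# Run with:  scpflow run-all -c examples/demo.yaml
outdir: demo_run
seed: 42
design:
  n_experimental: 8
  n_control: 8
  n_sessions: 8
  phase_break_session: 4
  trials_per_session: 24
draws: 500
warmup: 300
chains: 2
plots: true
# raw-epoch stage (optional, slower):
simulate_epochs: false
epoch_participants: 2
epoch_sessions: [1, 2, 3, 4]
psd: false
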