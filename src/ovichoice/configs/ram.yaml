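# Ram-scenario pipeline: study-sized simulation and estimation defaults.
scenario: ram
design_runs: 16
design_blocks: 4
design_resolution: 4
design_seed: 11
n_respondents: 370
simulate_seed: 22
n_draws: 500
draw_scheme: halton
gamma: 0.0
estimate_seed: 33
drop_alternative: 2
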