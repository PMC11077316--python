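# Default desk-scale configuration: the full synthetic scenario with all
# five stages. Override any field; see regenscreen.pipeline.RunConfig.
seed: 7
outdir: regenscreen_out
stages: [simulate, screen, tree, tfbs, expr]
n_wbr: 3
n_hra: 5
n_lra: 8
n_confirm: 2
n_background: 200
n_cbr: 10
n_paralog: 10
divergence: 0.05
evalue_max_loss: 1.0e-4
score_min_hra: 100
n_bootstrap: 100
windows: [100, 500, 1000, 3000, 5000, 7500]
plant_rate_target: 0.8
plant_rate_background: 0.1
noise_sd: 0.25
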