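# Pipeline configuration: simulate the short-segment fixture and analyse it.
# Run:  fiberhop report --config config/fig3d_analysis.yaml --out scratch/run
fixture: fig3d
noise: 0.02
seed: 0
T_min_arrhenius: 100.0        # K, high-temperature fit window floor
power_law_T_range: [20.0, 100.0]
crossover_threshold: 0.20
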