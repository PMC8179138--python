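# Harmonic alchemical demo: k 1 -> 2 kcal/mol/A^2, exact ddG = (kT/2) ln 2
seed: 42
outdir: results/demo
n_windows: 24
n_steps: 20000
n_replicates: 3
temperatures: [280, 285, 290, 295, 300, 305, 310, 315]
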