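k_ox: 234.0
n_boot: 2000
ph: 6.2
sim_n_cells: 60
sim_replicates: 3
sim_true_e_gsh_mV: -157.0
sim_true_gsh_M: 0.0027
sim_true_sh_to_ssg: 0.06
temperature_K: 310.15
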