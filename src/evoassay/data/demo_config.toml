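seed = 1
out_dir = "pipeline_out"
stages = ["synthetic", "flow", "gradient", "dose", "evolve", "summary"]
smoothing_window = 500
control_responder_fraction = 0.3
mutant_responder_fraction = 0.18
flow_shift = 1.2
flow_events = 10000
auc_axis = "log10"
top_conc_uM = 30.0
dilution = 3.0
n_dose_points = 12
mutant_top_scale = 0.6
sensitivity_target_nM = 41.0
mi_lo = 4.0
cons_lo = -0.5
mi_hi = 8.0
cons_hi = -0.3
select_fraction = 0.005
evolve_taxa = 12
evolve_sites = 60
evolve_branch_length = 0.15
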