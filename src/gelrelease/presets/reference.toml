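# Reference release assay: EGF premixed in a heparin-based hydrogel in a
# 12-well plate, protein-free media exchanged daily for three days at 37 degC.

[transport]
temperature_K = 310.15
viscosity_Pa_s = 6.913e-4
molecular_weight_g_mol = 6200.0
binder_concentration_kg_m3 = 4.0
binder_diffusivity_m2_s = 0.0
porosity = 0.69
bound_fraction = 0.995
initial_concentration_ng_mL = 50.0

[geometry]
# nominal growth area of a 12-well plate; 1.5 mL gel under 1.5 mL media
cross_section_area_m2 = 3.8e-4
gel_volume_m3 = 1.5e-6
media_volume_m3 = 1.5e-6

[protocol]
horizon_h = 72.0
exchange_times_h = [24.0, 48.0, 72.0]

[solver]
n_cells_gel = 60
n_cells_media = 60
dt_s = 60.0
scheme = "implicit"
mass_tolerance = 1e-8
media_mode = "diffusive"
perfect_sink = false

[reference]
# reported values of the study this preset encodes, for comparison reports
measured_retention_percent = 96.73
measured_retention_sem_percent = 0.53
simulated_retention_percent = 96.0
max_cumulative_release_percent = 5.0
binding_percent = 99.5
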