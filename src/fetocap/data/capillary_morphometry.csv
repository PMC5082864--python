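label,villous_volume_um3,villous_area_um2,cap_volume_fraction,cap_area_fraction,L_um,L_path_um,d_um,d_sd_um,u_max_at_0p5Pa_um_per_s,R_resistance_Pa_s_per_um3,R_cap_Pa_s_per_um6,R_vil_Pa_s_per_um6,N_max_numeric_ug_per_s,N_max_annular_ug_per_s,N_ratio_0p5Pa,N_ratio_20Pa
image1,6.88e4,8.01e3,0.185,0.680,185,147,51,19,45,5.8e-4,4.58e-8,8.4e-8,3.2e-6,1.8e-6,0.83,0.28
image2,5.62e4,7.55e3,0.340,0.862,164,164,15,10,38,4.0e-4,2.1e-8,7.1e-9,6.6e-6,3.3e-6,0.90,0.39
image3,2.54e4,3.96e3,0.255,0.674,92,80,22,11,53,3.0e-4,4.7e-8,1.2e-8,2.7e-6,1.2e-6,0.84,0.26
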