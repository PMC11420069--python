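name,quantum_efficiency,npp_fraction,t_min,t_opt,t_max,vpd_coeff,max_age,allom_a,allom_b,n_conc_foliage,n_conc_root,n_conc_stem,p_to_n_ratio,sla,extinction_k,wood_density
eucalypt,9.0e-07,0.47,8.0,25.0,40.0,0.5,50.0,0.095,2.4,24.0,10.0,4.0,0.10,11.0,0.5,0.50
poplar,8.0e-07,0.47,-2.0,18.0,35.0,0.6,40.0,0.12,2.3,28.0,12.0,5.0,0.12,14.0,0.5,0.35
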