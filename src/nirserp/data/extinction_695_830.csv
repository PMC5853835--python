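wavelength_nm,species,epsilon_per_mM_mm
695,oxy,0.0320
695,deoxy,0.1920
830,oxy,0.0974
830,deoxy,0.0693
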