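interval,upper_m,lower_m,area_1e12_m2,cox_mmol_m2_d
shelf,0,200,27.12,9.4
upper_slope,200,1000,16.01,3.0
lower_slope,1000,2000,15.84,1.5
deep_sea,2000,11000,302.5,0.45
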