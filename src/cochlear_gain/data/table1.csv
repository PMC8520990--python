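participant,masker_freq_kHz,masker_level_dB,precursor_class,precursor_level_dB,mean_threshold_dB,sd_dB,n_runs,matched_pair,printed_significant
P1,2.4,65,none,,23.53,1.60,2,65,0
P1,4.0,16,none,,22.97,0.20,2,65,0
P1,2.4,65,on_tone,40,33.17,0.24,2,65,1
P1,4.0,16,on_tone,40,27.67,0.94,2,65,0
P1,2.4,75,none,,30.20,4.53,2,75,0
P1,4.0,33,none,,29.98,1.21,2,75,0
P1,2.4,75,on_tone,40,40.42,3.24,2,75,0
P1,4.0,33,on_tone,40,35.85,0.68,2,75,0
P2,2.4,65,none,,28.65,1.09,4,65,0
P2,4.0,21,none,,33.85,11.54,4,65,0
P2,2.4,65,on_tone,40,50.80,2.90,4,65,1
P2,4.0,21,on_tone,40,36.42,1.89,4,65,0
P2,2.4,80,none,,45.41,4.59,4,80,0
P2,4.0,45,none,,51.68,5.56,4,80,0
P2,2.4,80,on_tone,40,68.36,9.77,4,80,0
P2,4.0,45,on_tone,40,57.89,2.31,4,80,0
P3,2.4,75,none,,25.25,1.06,2,75,0
P3,4.0,14,none,,22.30,0.42,2,75,0
P3,2.4,75,on_tone,40,52.40,7.07,2,75,0
P3,4.0,14,on_tone,40,26.27,0.09,2,75,0
P3,2.4,80,none,,31.61,1.15,2,80,0
P3,4.0,30,none,,29.72,0.08,2,80,0
P3,2.4,80,on_tone,40,50.77,2.27,2,80,1
P3,4.0,30,on_tone,40,35.16,0.79,2,80,0
P4,2.4,75,none,,29.93,1.52,2,75,0
P4,4.0,28,none,,30.76,1.28,2,75,0
P4,2.4,75,on_tone,40,45.60,1.98,2,75,0
P4,4.0,28,on_tone,40,39.24,4.38,2,75,0
P4,2.4,80,none,,36.18,1.44,2,80,0
P4,4.0,37,none,,41.81,3.37,2,80,0
P4,2.4,80,on_tone,40,48.46,0.94,2,80,0
P4,4.0,37,on_tone,40,43.93,3.21,2,80,0
P5,2.4,65,none,,27.12,3.84,2,65,0
P5,4.0,21,none,,26.08,4.36,2,65,0
P5,2.4,65,on_tone,40,43.48,2.17,3,65,1
P5,4.0,21,on_tone,40,32.19,0.04,2,65,0
P5,2.4,75,none,,28.89,1.97,2,75,0
P5,4.0,27,none,,29.78,1.96,2,75,0
P5,2.4,75,on_tone,40,46.78,1.96,2,75,1
P5,4.0,27,on_tone,40,33.54,0.05,2,75,0
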