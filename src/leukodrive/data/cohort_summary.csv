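variable,mean,sd,min,max
age,77.88,3.77,,
dsp_p1,5.8,1.5,3,9
dsp_p2,11.1,1.0,7,12
dsp_p3,2.5,1.2,2,6
dsp_p4,4.9,1.4,2,6
dsp_p5,4.5,1.1,2,6
dsp_p6,9.6,1.6,4,12
dsp_total,38.3,4.8,26,51
dvc_tracking,89.6,5.6,72,98
dvc_sudden,92.9,5.4,76,99
brain_atrophy,0.23,0.02,0.16,0.29
la_frontal,0.62,1.77,0,14.83
la_temporal,0.02,0.04,0,0.25
la_parietal,0.14,0.39,0,2.26
la_occipital,0.001,0.004,0,0.04
la_periventricular,14.6,14.5,0.5,89.5
la_total,14.7,15.8,0.46,102.5
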