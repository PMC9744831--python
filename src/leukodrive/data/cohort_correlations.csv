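,age,dsp_p1,dsp_p2,dsp_p3,dsp_p4,dsp_p5,dsp_p6,dsp_total,dvc_tracking,dvc_sudden,brain_atrophy,la_frontal,la_temporal,la_parietal,la_occipital,la_periventricular,la_total
age,1.00,-0.09,-0.16,-0.13,-0.02,-0.07,0.06,-0.09,-0.21,-0.18,0.35,0.19,0.06,0.20,0.12,0.33,0.33
dsp_p1,-0.09,1.00,0.31,0.22,0.25,0.13,0.20,0.59,0.13,0.11,0.15,-0.12,0.02,-0.11,-0.05,-0.05,-0.06
dsp_p2,-0.16,0.31,1.00,0.17,0.14,0.37,0.49,0.63,0.03,0.30,-0.06,-0.09,-0.03,-0.16,-0.06,-0.07,-0.08
dsp_p3,-0.13,0.22,0.17,1.00,0.04,0.34,0.22,0.51,0.05,0.05,0.03,-0.07,-0.02,-0.12,-0.04,-0.04,-0.04
dsp_p4,-0.02,0.25,0.14,0.04,1.00,0.21,0.36,0.57,0.18,-0.02,-0.06,-0.17,-0.18,-0.20,-0.01,-0.16,-0.16
dsp_p5,-0.07,0.13,0.37,0.34,0.21,1.00,0.48,0.66,-0.07,-0.02,-0.10,0.01,0.03,-0.05,-0.07,0.07,0.06
dsp_p6,0.06,0.20,0.49,0.22,0.36,0.48,1.00,0.77,0.01,0.03,0.07,-0.10,-0.08,-0.12,0.02,0.02,0.00
dsp_total,-0.09,0.59,0.63,0.51,0.57,0.66,0.77,1.00,0.10,0.11,0.02,-0.15,-0.08,-0.20,0.05,-0.06,-0.08
dvc_tracking,-0.21,0.13,0.03,0.05,0.18,-0.07,0.01,0.10,1.00,0.50,-0.18,-0.20,-0.19,-0.17,-0.09,-0.21,-0.22
dvc_sudden,-0.18,0.11,0.30,0.05,-0.02,-0.02,0.03,0.11,0.50,1.00,-0.27,-0.10,-0.13,-0.11,-0.25,-0.16,-0.16
brain_atrophy,0.35,0.15,-0.06,0.03,-0.06,-0.10,0.07,0.02,-0.18,-0.27,1.00,-0.01,-0.17,-0.04,-0.05,0.16,0.15
la_frontal,0.19,-0.12,-0.09,-0.07,-0.17,0.01,-0.10,-0.15,-0.20,-0.10,-0.01,1.00,0.73,0.86,0.19,0.78,0.82
la_temporal,0.06,0.02,-0.03,-0.02,-0.18,0.03,-0.08,-0.08,-0.19,-0.13,-0.17,0.73,1.00,0.69,0.31,0.54,0.57
la_parietal,0.20,-0.11,-0.16,-0.12,-0.20,-0.05,-0.12,-0.20,-0.17,-0.11,-0.04,0.86,0.69,1.00,0.29,0.79,0.83
la_occipital,0.12,-0.05,-0.06,-0.04,-0.01,-0.07,0.02,0.05,-0.09,-0.25,-0.05,0.19,0.31,0.29,1.00,0.17,0.18
la_periventricular,0.33,-0.05,-0.07,-0.04,-0.16,0.07,0.02,-0.06,-0.21,-0.16,0.16,0.78,0.54,0.79,0.17,1.00,1.00
la_total,0.33,-0.06,-0.08,-0.04,-0.16,0.06,0.00,-0.08,-0.22,-0.16,0.15,0.82,0.57,0.83,0.18,1.00,1.00
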