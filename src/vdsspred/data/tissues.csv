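tissue,volume_L,f_nl,f_np,f_ew,f_iw,albumin_ratio,lipoprotein_ratio
adipose,10.43,0.853,0.0016,0.135,0.017,0.049,0.068
bone,9.07,0.0174,0.0016,0.1,0.346,0.1,0.05
brain,1.49,0.0391,0.0015,0.162,0.62,0.048,0.041
gut,1.85,0.0375,0.0124,0.282,0.475,0.158,0.141
heart,0.31,0.0135,0.0106,0.32,0.456,0.157,0.16
kidney,0.31,0.0121,0.024,0.273,0.483,0.13,0.137
liver,2.52,0.0135,0.0238,0.161,0.573,0.086,0.161
lung,0.92,0.0215,0.0123,0.336,0.446,0.212,0.168
muscle,33.89,0.01,0.0072,0.118,0.63,0.064,0.059
pancreas,0.21,0.0403,0.009,0.12,0.664,0.06,0.06
skin,5.63,0.0603,0.0044,0.382,0.291,0.277,0.096
spleen,0.2,0.0071,0.0107,0.207,0.579,0.097,0.207
thymus,0.039,0.0168,0.0092,0.15,0.626,0.075,0.075
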