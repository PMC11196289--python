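name,ionization_class,pKa,fup,bpr,logp_admet,logp_literature,logp_hplc,hbd,hba,n_so,n_no2,dipole,observed_vdss_L
griseofulvin,neutral,,0.16,0.776,2.511,3.53,3.566,0,6,0,0,,107
itraconazole,weak_base,4.57,0.002,0.665,4.893,5.66,6.888,0,9,0,0,,800
posaconazole,weak_base,4.67,0.02,0.668,4.405,5.36,6.716,1,8,0,0,,294
isavuconazole,weak_base,3.28,0.01,0.737,3.619,3.56,4.934,1,6,0,0,,304
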