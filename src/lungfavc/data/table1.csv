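subject,height_cm,weight_kg,fev1_l,frc_ml
P00,185,91,4.82,3080
P01,180,83,5.24,3170
P02,174,56,4.27,3370
P03,171,75,4.68,3343
P04,173,80,3.88,2800
H01,174,82,4.85,2360
H02,187,88,5.57,4800
H03,177,78,4.27,3170
H04,186,87,5.48,4170
H05,173,80,3.76,3480
H06,179,,4.98,2910
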