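name,tr_s,mb,sense,vx_mm,vy_mm,vz_mm,gap_mm,flip_deg,n_volumes,n_slices
MB1S23x3x3.32.00,2.00,1,2,3.0,3.0,3.3,0.33,75,245,36
MB1S22.7iso2.45,2.45,1,2,2.7,2.7,2.7,0.27,79,200,44
MB2S22.7iso1.22,1.22,2,2,2.7,2.7,2.7,0.27,64,400,44
MB4S1.52.7iso0.70,0.70,4,1.5,2.7,2.7,2.7,0.27,51,700,44
MB4S22.7iso0.63,0.63,4,2,2.7,2.7,2.7,0.27,50,780,44
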