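patient_id,t_days,modality,radius_mm
virtual_diffuse,0.0,T1Gd,20.863288638320725
virtual_diffuse,0.0,T2,36.3260781207916
virtual_diffuse,60.0,T1Gd,23.459226101840787
virtual_diffuse,60.0,T2,38.386599370006586
virtual_diffuse,120.0,T1Gd,27.569902145411746
virtual_diffuse,120.0,T2,42.33820997874086
virtual_diffuse,180.0,T1Gd,30.000836882402123
virtual_diffuse,180.0,T2,45.27208096540928
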