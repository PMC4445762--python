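patient_id,t_days,modality,radius_mm
virtual_nodular,0.0,T1Gd,19.729018022371417
virtual_nodular,0.0,T2,23.31377209865917
virtual_nodular,60.0,T1Gd,21.761766844855444
virtual_nodular,60.0,T2,26.481188015185648
virtual_nodular,120.0,T1Gd,25.624090303812974
virtual_nodular,120.0,T2,28.23503083412865
virtual_nodular,180.0,T1Gd,27.751196321037543
virtual_nodular,180.0,T2,31.13741737221327
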