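key,label,rate_verbatim,rate_mm_per_s,c1_MPa,c2_MPa,c3_MPa
control-1.96,60-20-10-10 (1.96 mm/s),1.96 mm/s,1.96,0.0002,0.0090,0.0080
control-180,60-20-10-10 (180 mm/s),180 mm/s,180,0.0050,0.0100,0.0120
control-1800,60-20-10-10 (1800 mm/s),1800 mm/s,1800,0.7200,0.3500,0.8800
plantar-pain,Plantar pain (1.96 mm/s),1.96 mm/s,1.96,0.0004,0.0090,0.0100
diabetes,Diabetes (1.96 mm/min),1.96 mm/min,1.96,0.0006,0.0150,0.0100
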