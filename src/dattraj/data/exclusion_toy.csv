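subject_id,group,sex,age_at_visit,disease_duration,sbr_putamen_left,sbr_putamen_right,sbr_caudate_left,sbr_caudate_right
S01,sPD,M,61.0,1.0,0.70,0.95,1.40,1.60
S01,sPD,M,63.0,3.0,0.60,0.90,1.35,1.55
S02,sPD,F,61.0,1.0,0.80,1.05,1.45,1.65
S02,sPD,F,63.0,3.0,0.76,1.00,1.42,1.62
S03,sPD,M,61.0,1.0,1.70,1.90,2.10,2.30
S03,sPD,M,63.0,3.0,1.74,1.92,2.12,2.31
S04,sPD,F,61.0,1.0,1.62,1.80,2.00,2.20
S04,sPD,F,63.0,3.0,1.50,1.75,1.95,2.15
S05,sPD,M,61.0,1.0,0.55,0.90,1.30,1.50
S05,sPD,M,63.0,3.0,0.58,0.85,1.28,1.48
S06,sPD,F,61.0,1.0,1.00,1.20,1.60,1.80
S06,sPD,F,63.0,3.0,0.90,1.15,1.55,1.75
S07,sPD,M,61.0,1.0,1.65,1.95,2.05,2.35
S07,sPD,M,63.0,3.0,1.75,2.00,2.10,2.38
S08,sPD,F,61.0,1.0,0.66,0.98,1.35,1.58
S08,sPD,F,63.0,3.0,0.58,0.92,1.30,1.52
S09,sPD,M,61.0,1.0,1.40,1.55,1.85,2.00
S09,sPD,M,63.0,3.0,1.46,1.60,1.88,2.02
S10,sPD,F,61.0,1.0,0.75,0.85,1.38,1.48
S10,sPD,F,63.0,3.0,0.70,0.82,1.34,1.45
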