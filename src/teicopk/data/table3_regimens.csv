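gfr,label,day1_dose,day1_interval,day2_dose,day2_interval,day3_dose,day3_interval,maint_dose,maint_interval,weight_kg,infusion_duration_h
120,15q12h/15q24h/15q24h/15q24h,15,12,15,24,15,24,15,24,65,1.0
120,15q12h/15q12h/15q24h/7.5q24h,15,12,15,12,15,24,7.5,24,65,1.0
120,15q12h/15q12h/15q24h/15q24h,15,12,15,12,15,24,15,24,65,1.0
90,15q12h/15q24h/15q24h/15q24h,15,12,15,24,15,24,15,24,65,1.0
90,15q12h/15q12h/15q24h/7.5q24h,15,12,15,12,15,24,7.5,24,65,1.0
90,15q12h/15q12h/15q24h/15q24h,15,12,15,12,15,24,15,24,65,1.0
60,15q12h/15q24h/15q24h/7.5q24h,15,12,15,24,15,24,7.5,24,65,1.0
60,15q12h/15q24h/15q24h/15q48h,15,12,15,24,15,24,15,48,65,1.0
30,15q12h/15q24h/15q24h/7.5q24h,15,12,15,24,15,24,7.5,24,65,1.0
30,15q12h/15q24h/15q24h/15q48h,15,12,15,24,15,24,15,48,65,1.0
15,12q12h/12q24h/12q24h/12q72h,12,12,12,24,12,24,12,72,65,1.0
15,15q12h/15q24h/15q24h/5q24h,15,12,15,24,15,24,5,24,65,1.0
15,15q12h/15q24h/15q24h/15q72h,15,12,15,24,15,24,15,72,65,1.0
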