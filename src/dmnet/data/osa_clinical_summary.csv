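variable,label,mean_osa,sd_osa,n_osa,mean_gs,sd_gs,n_gs,t_published,t_recomputable
bmi,"BMI, kg/m^2",27.52,3.30,46,23.09,1.96,46,7.827,1
ahi,"AHI, events/h",58.26,20.37,46,2.51,1.21,46,18.529,1
total_sleep_time,"Total sleep time, min",372.26,83.88,46,398.30,18.94,46,-2.054,1
stage1_pct,"Stage 1, %",31.28,17.38,46,10.22,3.72,46,8.037,1
stage2_pct,"Stage 2, %",39.12,14.78,46,40.74,7.05,46,-0.672,1
stage34_pct,"Stages 3+4, %",22.49,18.21,46,21.15,4.54,46,0.483,0
rem_pct,"REM, %",7.29,7.96,46,21.89,7.48,46,-9.070,1
arousal_index,"Arousal index, events/h",40.36,23.63,46,11.93,2.79,46,8.102,1
sao2_below90_pct,"SaO2 < 90%, % of sleep time",31.15,21.34,46,0.27,0.17,46,9.813,1
average_sao2,"Average SaO2, %",90.69,4.46,46,95.59,2.41,46,-6.547,0
oxygen_desaturation_index,"Oxygen desaturation index, events/h",54.42,25.51,46,2.84,1.40,46,14.897,0
nadir_sao2,"Nadir SaO2, %",66.26,12.46,46,90.33,2.88,46,-12.765,1
moca,"MoCA score, points",25.17,2.11,46,27.74,1.39,46,-6.883,1
visuospatial_executive,"MoCA visuospatial/executive, points",4.07,0.83,46,4.67,0.63,46,-3.960,0
delayed_memory,"MoCA delayed memory, points",3.20,1.17,46,4.85,0.36,46,-9.172,0
attention,"MoCA attention, points",5.33,0.99,46,5.83,0.38,46,-3.194,0
language,"MoCA language, points",2.04,0.56,46,2.83,0.38,46,-7.860,0
abstraction,"MoCA abstraction, points",1.50,0.51,46,1.85,0.36,46,-3.790,0
orientation,"MoCA orientation, points",5.72,0.66,46,5.93,0.25,46,-2.102,0
ess,"ESS score, points",12.11,3.84,46,3.39,2.18,46,13.405,0
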