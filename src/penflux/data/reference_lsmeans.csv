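variable,dose_0,dose_1_38,dose_5_5,dose_22,sem,p_interaction,p_dose,p_vs_con_1_38,p_vs_con_5_5,p_vs_con_22
nh3_g_per_animal_d0_91,7783,7093,6860,6751,855,0.281,0.052,0.076,0.023,0.013
nh3_g_per_kg_bw_d0_91,13.6,12.1,11.7,11.6,1.19,0.161,0.004,0.009,0.002,0.001
nh3_g_per_kg_hcw_d0_91,22.3,19.5,18.7,18.5,1.97,0.147,0.001,0.004,0.001,0.001
nh3_g_per_animal_d0_7,415,394,387,326,49,0.746,0.022,0.439,0.300,0.004
nh3_g_per_animal_d0_14,953,835,801,699,106,0.802,0.006,0.062,0.020,0.001
nh3_g_per_animal_d0_28,2097,1783,1686,1563,265,0.573,0.006,0.027,0.006,0.001
nh3_g_per_animal_d0_56,4619,4089,3888,3763,540,0.420,0.019,0.050,0.011,0.004
final_bw_kg,567,583,582,582,19.4,0.916,0.257,,,
initial_bw_kg,451,454,455,452,10.0,0.996,0.937,,,
hcw_kg,349,364,365,365,11.7,0.865,0.035,0.019,0.014,0.014
dressing_pct,61.5,62.4,62.7,62.8,0.34,0.738,0.002,0.006,0.001,0.001
dmi_kg_d,8.8,9.2,8.8,8.8,0.56,0.980,0.585,,,
adg_kg_d,1.27,1.42,1.39,1.43,0.126,0.724,0.075,0.027,0.067,0.023
gf_kg_kg,0.144,0.156,0.158,0.163,0.0071,0.856,0.031,0.065,0.033,0.005
marbling,623,573,560,562,16.7,0.979,0.058,0.051,0.018,0.022
wbsf_kg,2.48,2.79,2.92,2.75,0.117,0.620,0.017,0.022,0.003,0.039
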