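code,weight,median_lot_days,lot_sigma,p_post_discharge,share_post_discharge,share_sd
UTI-cystitis,420,6.5,0.40,0.55,0.63,0.21
UTI-complicated,241,12.0,0.40,0.68,0.63,0.18
UTI-CAD,28,11.0,0.40,0.54,0.65,0.18
UTI-kidney_transplant,47,11.0,0.40,0.60,0.59,0.17
UTI-other,89,13.0,0.40,0.67,0.68,0.18
RTI-CAP_mild_moderate,328,6.0,0.40,0.43,0.54,0.20
RTI-CAP_severe,90,5.0,0.40,0.19,0.46,0.24
RTI-HAP,41,6.0,0.40,0.15,0.37,0.24
RTI-aspiration,82,6.5,0.40,0.28,0.51,0.20
RTI-COPD,73,6.0,0.40,0.44,0.58,0.18
RTI-abscess_empyema,23,8.0,0.40,0.39,0.55,0.19
RTI-other,154,6.0,0.40,0.33,0.56,0.17
CNS,51,8.0,0.40,0.14,0.70,0.21
CVL,29,7.0,0.40,0.38,0.59,0.17
ENT,106,10.0,0.40,0.83,0.63,0.14
gastroenteritis,40,5.0,0.40,0.35,0.60,0.21
gynaecological,165,7.0,0.40,0.55,0.68,0.16
intraabdominal,464,6.0,0.40,0.31,0.52,0.19
sepsis_unknown,270,4.0,0.40,0.20,0.56,0.20
SSTI,336,11.0,0.40,0.64,0.62,0.19
other,157,6.0,0.40,0.31,0.63,0.19
prophylaxis,0,4.0,0.40,0.30,0.60,0.20
bone_joint_infection,0,14.0,0.40,0.60,0.60,0.20
s_aureus_bacteraemia,0,14.0,0.40,0.50,0.60,0.20
endovascular_infection,0,14.0,0.40,0.50,0.60,0.20
eye_infection,0,10.0,0.40,0.40,0.60,0.20
febrile_neutropenia,0,10.0,0.40,0.30,0.60,0.20
fungal_infection,0,14.0,0.40,0.40,0.60,0.20
mediastinitis,0,14.0,0.40,0.40,0.60,0.20
UTI-cyst_infection,0,14.0,0.40,0.50,0.60,0.20
chronic_prostatitis,0,14.0,0.40,0.60,0.60,0.20
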