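code,tract,specification,long_treatment
UTI-cystitis,UTI,cystitis,0
UTI-complicated,UTI,complicated,0
UTI-CAD,UTI,CAD,0
UTI-kidney_transplant,UTI,kidney_transplant,0
UTI-other,UTI,other,0
RTI-CAP_mild_moderate,RTI,CAP_mild_moderate,0
RTI-CAP_severe,RTI,CAP_severe,0
RTI-HAP,RTI,HAP,0
RTI-aspiration,RTI,aspiration,0
RTI-COPD,RTI,COPD,0
RTI-abscess_empyema,RTI,abscess_empyema,0
RTI-other,RTI,other,0
CNS,CNS,,0
CVL,CVL,,0
ENT,ENT,,0
gastroenteritis,gastroenteritis,,0
gynaecological,gynaecological,,0
intraabdominal,intraabdominal,,0
sepsis_unknown,sepsis_unknown,,0
SSTI,SSTI,,0
other,other,,0
prophylaxis,prophylaxis,,0
bone_joint_infection,bone_joint_infection,,1
s_aureus_bacteraemia,s_aureus_bacteraemia,,1
endovascular_infection,endovascular_infection,,1
eye_infection,eye_infection,,1
febrile_neutropenia,febrile_neutropenia,,1
fungal_infection,fungal_infection,,1
mediastinitis,mediastinitis,,1
UTI-cyst_infection,UTI,cyst_infection,1
chronic_prostatitis,chronic_prostatitis,,1
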