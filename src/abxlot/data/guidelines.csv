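code,min_days,max_days
UTI-cystitis,3,7
UTI-complicated,7,14
UTI-CAD,7,14
RTI-CAP_mild_moderate,5,5
RTI-CAP_severe,5,5
RTI-HAP,5,7
RTI-aspiration,5,5
RTI-COPD,7,7
ENT,7,14
SSTI,10,14
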