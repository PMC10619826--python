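category,coding_system,code
annual_review,synthetic,AREV001
breathlessness,synthetic,BRTH001
consultation,synthetic,CONS001
copd_diagnosis,synthetic,COPD001
copd_diagnosis,synthetic,COPD002
cough,synthetic,COUGH001
exacerbation,synthetic,EXAC001
exacerbation,synthetic,EXAC002
exacerbation,synthetic,EXAC003
heart_failure,synthetic,HF001
lrti,synthetic,LRTI001
lrti,synthetic,LRTI002
ocs,synthetic,OCS001
ocs,synthetic,OCS002
resp_antibiotic,synthetic,RABX001
resp_antibiotic,synthetic,RABX002
smoking_current,synthetic,SMOKCUR1
smoking_ex,synthetic,SMOKEX1
smoking_never,synthetic,SMOKNEV1
sputum,synthetic,SPUT001
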