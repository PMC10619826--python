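patient_id,admission_date,episode_id,icd10_code,position
P000001,2012-09-05,1,I109,1
P000001,2012-09-05,1,J441,2
P000002,2013-04-18,2,J449,1
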