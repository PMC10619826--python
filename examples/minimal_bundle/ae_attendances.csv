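patient_id,attendance_date,diagnosis_category
P000001,2012-09-05,resp_nonasthma
P000002,2014-07-01,bronchial_asthma
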