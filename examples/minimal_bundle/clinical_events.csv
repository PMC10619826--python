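patient_id,event_date,code
P000001,2006-02-01,CONS001
P000001,2006-02-01,SMOKCUR1
P000001,2008-03-01,COPD001
P000001,2012-03-01,EXAC001
P000001,2012-03-01,LRTI001
P000001,2013-01-15,AREV001
P000001,2013-01-15,EXAC001
P000002,2006-02-01,CONS001
P000002,2006-02-01,SMOKEX1
P000002,2011-01-20,HF001
P000002,2011-05-10,COPD001
P000002,2012-06-10,COUGH001
P000002,2012-06-10,SPUT001
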