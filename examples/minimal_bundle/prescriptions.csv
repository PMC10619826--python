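patient_id,issue_date,code,duration_days
P000001,2014-02-02,OCS002,10.0
P000002,2012-06-10,OCS001,7.0
P000002,2012-06-10,RABX001,7.0
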