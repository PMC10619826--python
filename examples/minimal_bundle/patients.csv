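patient_id,birth_date,sex,region,imd_quintile,registration_start,registration_end,death_date,linkage_eligible
P000001,1951-04-02,male,London,2,2005-01-01,,,True
P000002,1946-11-20,female,Northwest,4,2005-01-01,2016-08-31,,True
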