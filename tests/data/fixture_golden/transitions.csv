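patient_id,from_pattern,to_pattern,transition_date,from_ordinal
P02,L-dopa,L-dopa+MAOBI,2018-09-06,1
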