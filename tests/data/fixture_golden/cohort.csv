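patient_id,index_date,age_at_index,age_group,age_group_coarse,new_initiator,observation_end,eligible,exclusion_reasons
P01,2018-03-01,72,65-74,<75,True,2021-05-31,True,
P02,2018-03-01,80,75-84,>=75,True,2021-05-31,True,
P03,2018-03-01,29,<65,<75,False,2021-05-31,False,age
P04,2018-03-01,67,65-74,<75,False,2021-05-31,True,
P05,2018-03-01,70,65-74,<75,False,2021-05-31,False,rx_count
P06,2018-03-01,73,65-74,<75,False,2021-05-31,True,
P07,2018-03-01,58,<65,<75,True,2021-05-31,True,
P08,2018-03-01,77,75-84,>=75,False,2021-05-31,True,
P09,2018-03-01,70,65-74,<75,False,2021-05-31,False,pd_followup
P10,2018-03-01,74,65-74,<75,True,2021-05-31,True,
P11,2018-03-01,72,65-74,<75,True,2021-05-31,True,
P12,2018-03-01,75,75-84,>=75,True,2021-05-31,True,
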