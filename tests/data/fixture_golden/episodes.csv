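patient_id,drug_class,start,end,duration_days,n_claims,total_supplied_days
P01,L-dopa,2018-03-10,2018-11-05,240,8,240
P02,L-dopa,2018-03-10,2019-01-04,300,10,300
P02,MAOBI,2018-09-06,2019-01-04,120,4,120
P04,L-dopa,2018-03-10,2018-07-08,120,4,120
P06,L-dopa,2018-03-10,2018-07-08,120,4,120
P07,NE-DA,2018-03-10,2018-09-06,180,6,180
P08,L-dopa,2018-03-10,2018-07-08,120,4,120
P10,L-dopa,2018-03-10,2018-09-06,180,3,90
P11,L-dopa,2018-03-10,2018-04-09,30,1,30
P11,L-dopa,2018-07-09,2018-09-07,60,2,60
P12,L-dopa,2018-03-10,2018-09-06,180,6,180
P12,NE-DA,2018-06-08,2018-06-13,5,1,5
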