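patient_id,pattern,start,end,duration_days,ordinal
P01,L-dopa,2018-03-10,2018-11-05,240,1
P02,L-dopa,2018-03-10,2018-09-06,180,1
P02,L-dopa+MAOBI,2018-09-06,2019-01-04,120,2
P04,L-dopa,2018-03-10,2018-07-08,120,1
P06,L-dopa,2018-03-10,2018-07-08,120,1
P07,NE-DA,2018-03-10,2018-09-06,180,1
P08,L-dopa,2018-03-10,2018-07-08,120,1
P10,L-dopa,2018-03-10,2018-09-06,180,1
P11,L-dopa,2018-03-10,2018-04-09,30,1
P11,L-dopa,2018-07-09,2018-09-07,60,2
P12,L-dopa,2018-03-10,2018-09-06,180,1
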