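patient_id,sex,birth_ym,source,enroll_start,enroll_end,has_dbs_or_lcig
P01,female,1946-01-01,JMDC,2017-06-01,2021-05-31,false
P02,male,1937-05-01,ELDERLY,2017-06-01,2021-05-31,false
P03,male,1989-01-01,JMDC,2017-06-01,2021-05-31,false
P04,female,1950-06-01,JMDC,2018-01-01,2021-05-31,false
P05,male,1948-02-01,JMDC,2017-06-01,2021-05-31,false
P06,female,1944-09-01,JMDC,2017-06-01,2021-05-31,false
P07,male,1960-01-01,NHI,2017-06-01,2021-05-31,false
P08,female,1941-03-01,ELDERLY,2017-06-01,2021-05-31,false
P09,male,1947-07-01,JMDC,2017-06-01,2021-05-31,false
P10,female,1943-11-01,JMDC,2017-06-01,2021-05-31,false
P11,male,1945-04-01,JMDC,2017-06-01,2021-05-31,false
P12,female,1942-08-01,JMDC,2017-06-01,2021-05-31,false
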