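patient_id,icd10_code,claim_date
P01,G20,2018-03-10
P01,G20,2018-10-15
P01,G20,2019-04-02
P01,K59.0,2017-11-15
P02,F03,2017-12-10
P02,G20,2018-03-10
P02,G20,2018-11-05
P03,G20,2018-03-10
P03,G20,2018-10-15
P04,G20,2018-03-10
P04,G20,2018-10-15
P05,G20,2018-03-10
P05,G20,2018-10-15
P06,G20,2018-03-10
P06,G20,2018-10-15
P07,G20,2018-03-10
P07,G20,2018-10-15
P08,G20,2018-03-10
P08,G20,2018-10-15
P08,G21.1,2017-12-20
P09,G20,2018-03-10
P09,G20,2018-05-01
P10,G20,2018-03-10
P10,G20,2018-10-15
P11,G20,2018-03-10
P11,G20,2018-10-15
P12,G20,2018-03-10
P12,G20,2018-10-15
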