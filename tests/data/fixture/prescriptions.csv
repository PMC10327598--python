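patient_id,drug_code,dispense_date,days_supplied,daily_dose_mg
P01,N04BA02,2018-03-10,30,100
P01,N04BA02,2018-04-09,30,150
P01,N04BA02,2018-05-09,30,200
P01,N04BA02,2018-06-08,30,250
P01,N04BA02,2018-07-08,30,300
P01,N04BA02,2018-08-07,30,300
P01,N04BA02,2018-09-06,30,300
P01,N04BA02,2018-10-06,30,300
P02,N04BA02,2018-03-10,30,100
P02,N04BA02,2018-04-09,30,150
P02,N04BA02,2018-05-09,30,200
P02,N04BA02,2018-06-08,30,250
P02,N04BA02,2018-07-08,30,300
P02,N04BA02,2018-08-07,30,300
P02,N04BA02,2018-09-06,30,300
P02,N04BA02,2018-10-06,30,300
P02,N04BA02,2018-11-05,30,300
P02,N04BA02,2018-12-05,30,300
P02,N04BD02,2018-09-06,30,
P02,N04BD02,2018-10-06,30,
P02,N04BD02,2018-11-05,30,
P02,N04BD02,2018-12-05,30,
P03,N04BA02,2018-03-10,30,
P03,N04BA02,2018-04-09,30,
P03,N04BA02,2018-05-09,30,
P03,N04BA02,2018-06-08,30,
P04,N04BA02,2018-03-10,30,
P04,N04BA02,2018-04-09,30,
P04,N04BA02,2018-05-09,30,
P04,N04BA02,2018-06-08,30,
P05,N04BA02,2018-03-10,30,100
P06,N04BA02,2018-01-15,30,100
P06,N04BA02,2018-03-10,30,
P06,N04BA02,2018-04-09,30,
P06,N04BA02,2018-05-09,30,
P06,N04BA02,2018-06-08,30,
P07,N04BC05,2018-03-10,30,
P07,N04BC05,2018-04-09,30,
P07,N04BC05,2018-05-09,30,
P07,N04BC05,2018-06-08,30,
P07,N04BC05,2018-07-08,30,
P07,N04BC05,2018-08-07,30,
P08,N04BA02,2018-03-10,30,
P08,N04BA02,2018-04-09,30,
P08,N04BA02,2018-05-09,30,
P08,N04BA02,2018-06-08,30,
P09,N04BA02,2018-03-10,30,
P09,N04BA02,2018-04-09,30,
P09,N04BA02,2018-05-09,30,
P10,N04BA02,2018-03-10,30,100
P10,N04BA02,2018-07-08,30,100
P10,N04BA02,2018-08-07,30,100
P11,N04BA02,2018-03-10,30,100
P11,N04BA02,2018-07-09,30,100
P11,N04BA02,2018-08-08,30,100
P12,N04BA02,2018-03-10,30,100
P12,N04BA02,2018-04-09,30,100
P12,N04BA02,2018-05-09,30,100
P12,N04BA02,2018-06-08,30,100
P12,N04BA02,2018-07-08,30,100
P12,N04BA02,2018-08-07,30,100
P12,N04BC05,2018-06-08,5,
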