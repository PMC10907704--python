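characteristic,level,CDOX_n,CDOX_pct,DOXIL_n,DOXIL_pct,MYOCET_n,MYOCET_pct,Total_n,Total_pct
age_band,<18,1.0,2.44,2.0,5.26,0.0,0.0,3.0,3.75
age_band,18-64,19.0,46.34,22.0,57.89,6.0,46.15,41.0,51.25
age_band,>=65,8.0,19.51,6.0,15.79,3.0,23.08,15.0,18.75
age_band,unknown,13.0,31.71,8.0,21.05,4.0,30.77,21.0,26.25
sex,F,14.0,34.15,17.0,44.74,7.0,53.85,32.0,40.0
sex,M,16.0,39.02,12.0,31.58,3.0,23.08,26.0,32.5
sex,unknown,11.0,26.83,9.0,23.68,3.0,23.08,22.0,27.5
country,AT,0.0,0.0,1.0,2.63,0.0,0.0,1.0,1.25
country,CA,5.0,12.2,1.0,2.63,3.0,23.08,8.0,10.0
country,CN,0.0,0.0,1.0,2.63,0.0,0.0,1.0,1.25
country,DE,4.0,9.76,5.0,13.16,2.0,15.38,9.0,11.25
country,ES,0.0,0.0,1.0,2.63,0.0,0.0,1.0,1.25
country,FR,4.0,9.76,2.0,5.26,2.0,15.38,6.0,7.5
country,GB,2.0,4.88,5.0,13.16,1.0,7.69,6.0,7.5
country,IT,1.0,2.44,3.0,7.89,1.0,7.69,4.0,5.0
country,JP,1.0,2.44,3.0,7.89,0.0,0.0,4.0,5.0
country,OTHER,7.0,17.07,6.0,15.79,1.0,7.69,13.0,16.25
country,US,17.0,41.46,10.0,26.32,3.0,23.08,27.0,33.75
reporter,consumer,3.0,7.32,3.0,7.89,0.0,0.0,5.0,6.25
reporter,health-professional,7.0,17.07,5.0,13.16,1.0,7.69,11.0,13.75
reporter,physician,18.0,43.9,17.0,44.74,10.0,76.92,38.0,47.5
reporter,other health-professional,10.0,24.39,11.0,28.95,2.0,15.38,21.0,26.25
reporter,pharmacist,1.0,2.44,2.0,5.26,0.0,0.0,3.0,3.75
reporter,unknown,2.0,4.88,0.0,0.0,0.0,0.0,2.0,2.5
indication,Acute lymphocytic leukaemia,3.0,7.32,6.0,15.79,2.0,15.38,10.0,12.5
indication,Breast cancer,12.0,29.27,12.0,31.58,4.0,30.77,23.0,28.75
indication,Malignant lymphoma,5.0,12.2,6.0,15.79,4.0,30.77,12.0,15.0
indication,Multiple myeloma,12.0,29.27,5.0,13.16,2.0,15.38,19.0,23.75
indication,Ovarian cancer,9.0,21.95,9.0,23.68,1.0,7.69,16.0,20.0
reporting_year,2004-2007,10.0,24.39,10.0,26.32,7.0,53.85,24.0,30.0
reporting_year,2008-2011,16.0,39.02,7.0,18.42,2.0,15.38,20.0,25.0
reporting_year,2012-2015,6.0,14.63,10.0,26.32,3.0,23.08,16.0,20.0
reporting_year,2016-2019,4.0,9.76,3.0,7.89,0.0,0.0,7.0,8.75
reporting_year,2020-2022,5.0,12.2,8.0,21.05,1.0,7.69,13.0,16.25
age_years,mean,56.24,,47.98,,56.44,,52.04,
weight_kg,mean,67.09,,64.39,,60.8,,64.93,
Total,n,41.0,100.0,38.0,100.0,13.0,100.0,80.0,100.0
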