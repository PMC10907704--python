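soc,pt,drug_group,n,median_days,q1,q3,mean_days,mean_rank,test,statistic,p_value,significant
Blood and lymphatic system disorders,Anaemia,CDOX,1,48.0,48.0,48.0,48.0,1.0,not-performed,,,False
Cardiac disorders,Cardiotoxicity,DOXIL,2,55.5,42.25,68.75,55.5,1.5,not-performed,,,False
Cardiac disorders,Cardiotoxicity,MYOCET,1,102.0,102.0,102.0,102.0,3.0,not-performed,,,False
Gastrointestinal disorders,Nausea,CDOX,1,58.0,58.0,58.0,58.0,1.0,not-performed,,,False
Gastrointestinal disorders,Nausea,DOXIL,1,295.0,295.0,295.0,295.0,2.0,not-performed,,,False
General disorders and administration site conditions,Drug ineffective,CDOX,9,37.0,23.0,46.0,44.56,10.22,Kruskal-Wallis,1.0407040704070338,0.5943112926428766,False
General disorders and administration site conditions,Drug ineffective,DOXIL,11,56.0,26.0,94.0,69.18,13.0,Kruskal-Wallis,1.0407040704070338,0.5943112926428766,False
General disorders and administration site conditions,Drug ineffective,MYOCET,3,46.0,43.0,55.5,50.33,13.67,Kruskal-Wallis,1.0407040704070338,0.5943112926428766,False
General disorders and administration site conditions,Febrile neutropenia,CDOX,9,53.0,36.0,178.0,102.78,6.0,not-performed,,,False
General disorders and administration site conditions,Febrile neutropenia,MYOCET,1,3.0,3.0,3.0,3.0,1.0,not-performed,,,False
General disorders and administration site conditions,Pyrexia,CDOX,1,89.0,89.0,89.0,89.0,1.0,not-performed,,,False
Infections and infestations,Sepsis,CDOX,2,72.0,63.5,80.5,72.0,3.5,Mann-Whitney,4.0,0.7728299926844475,False
Infections and infestations,Sepsis,DOXIL,3,34.0,33.5,65.0,54.33,2.67,Mann-Whitney,4.0,0.7728299926844475,False
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",Malignant neoplasm progression,CDOX,1,80.0,80.0,80.0,80.0,2.0,not-performed,,,False
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",Malignant neoplasm progression,DOXIL,1,75.0,75.0,75.0,75.0,1.0,not-performed,,,False
"Respiratory, thoracic and mediastinal disorders",Pneumonia,CDOX,3,117.0,101.0,146.0,125.67,3.17,not-performed,,,False
"Respiratory, thoracic and mediastinal disorders",Pneumonia,DOXIL,1,14.0,14.0,14.0,14.0,1.0,not-performed,,,False
"Respiratory, thoracic and mediastinal disorders",Pneumonia,MYOCET,1,175.0,175.0,175.0,175.0,4.5,not-performed,,,False
Skin and subcutaneous tissue disorders,Palmar-plantar erythrodysaesthesia syndrome,CDOX,1,16.0,16.0,16.0,16.0,1.0,not-performed,,,False
Skin and subcutaneous tissue disorders,Palmar-plantar erythrodysaesthesia syndrome,DOXIL,8,68.5,27.5,80.25,63.75,5.5,not-performed,,,False
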