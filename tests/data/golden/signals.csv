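soc,pt_code,pt,drug_group,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ic,ic025,flag_ror,flag_prr,flag_bcpnn
Blood and lymphatic system disorders,10002034,Anaemia,CDOX,1,15,40,144,0.24,0.030762902779810846,1.8723850740705084,0.25853658536585367,2.166910102242942,-0.713695814843359,-3.341659377869959,False,False,False
Blood and lymphatic system disorders,10002034,Anaemia,DOXIL,1,15,37,147,0.2648648648648649,0.03389028506667725,2.0700149468161806,0.28421052631578947,1.8370200864480033,-0.6040713236688607,-3.262875550362277,False,False,False
Blood and lymphatic system disorders,10029354,Neutropenia,CDOX,2,6,39,153,1.3076923076923077,0.2540549935052617,6.731059082931258,1.2926829268292683,0.10354348826507147,0.8712666858777972,-1.870318394174633,False,False,False
Blood and lymphatic system disorders,10029354,Neutropenia,DOXIL,2,6,36,156,1.4444444444444444,0.2799625185648196,7.452496726283565,1.4210526315789473,0.1949317738791422,0.9808911770522953,-1.8059317111283255,False,False,False
Blood and lymphatic system disorders,10029354,Neutropenia,MYOCET,2,6,11,181,5.484848484848484,0.98990190354226,30.390448582929118,4.794871794871795,4.692856163444398,2.5283789723547887,-1.1544187273071997,False,False,False
Cardiac disorders,10048610,Cardiotoxicity,CDOX,1,12,40,147,0.30625,0.03865513957990384,2.4263025180941113,0.3231707317073171,1.399434327617105,-0.4141355329844512,-3.153078756889387,False,False,False
Cardiac disorders,10048610,Cardiotoxicity,DOXIL,2,11,36,151,0.7626262626262627,0.16188675392166987,3.5926275767362186,0.7751196172248804,0.11808701179186223,0.2804514589112031,-2.152569054879854,False,False,False
Cardiac disorders,10048610,Cardiotoxicity,MYOCET,3,10,10,177,5.31,1.2594500547434206,22.387628547718958,4.315384615384616,6.286582486161455,2.2429767534925404,-0.7482707227289624,True,True,False
Gastrointestinal disorders,10028813,Nausea,CDOX,2,5,39,154,1.5794871794871794,0.2952478159397509,8.449782235386483,1.551219512195122,0.28996832012647866,1.0639117638201931,-1.7920319294103062,False,False,False
Gastrointestinal disorders,10028813,Nausea,DOXIL,2,5,36,157,1.7444444444444445,0.3253323966876558,9.3537761708825,1.7052631578947368,0.43180297702613846,1.1735362549946913,-1.730533284728541,False,False,False
General disorders and administration site conditions,10017947,Drug ineffective,CDOX,22,88,19,71,0.9342105263157895,0.46910405586206255,1.8604599482206385,0.9695121951219513,0.03749723031821513,0.028506427688994352,-0.7668340286751294,False,False,False
General disorders and administration site conditions,10017947,Drug ineffective,DOXIL,17,93,21,69,0.6006144393241167,0.2949202340760286,1.2231704137045651,0.7792869269949066,1.9965739263984876,-0.21550603575120794,-1.094837747427047,False,False,False
General disorders and administration site conditions,10017947,Drug ineffective,MYOCET,5,105,8,82,0.4880952380952381,0.1539192342368491,1.547805007167921,0.684981684981685,1.536550199651805,-0.2529807411698709,-1.9111617893341024,False,False,False
General disorders and administration site conditions,10016288,Febrile neutropenia,CDOX,13,9,28,150,7.738095238095238,3.020257041553485,19.82550395215157,5.6016260162601625,22.58820410394633,1.6342274885769477,0.27102984374973826,True,True,True
General disorders and administration site conditions,10016288,Febrile neutropenia,DOXIL,3,19,35,143,0.6451127819548872,0.18071348597847808,2.302929962244972,0.6731301939058172,0.4620752501690802,-0.06350294230615806,-2.0225739996291283,False,False,False
General disorders and administration site conditions,10016288,Febrile neutropenia,MYOCET,3,19,10,168,2.6526315789473682,0.6709208320998389,10.487756463912751,2.271255060728745,2.0713889247206563,1.4839848529963353,-1.07507052977938,False,False,False
General disorders and administration site conditions,10037660,Pyrexia,CDOX,2,9,39,150,0.8547008547008547,0.1774338677280139,4.117103236154252,0.8617886178861789,0.038382643076614584,0.4118350672404999,-2.0919740539451297,False,False,False
General disorders and administration site conditions,10037660,Pyrexia,DOXIL,2,9,36,153,0.9444444444444444,0.1955848689152767,4.5605537564787815,0.9473684210526315,0.005063162957899807,0.521459558414998,-2.020940743389243,False,False,False
General disorders and administration site conditions,10037660,Pyrexia,MYOCET,1,10,12,177,1.475,0.17403540439561324,12.501048321492217,1.4384615384615387,0.1285701820461179,1.4839848529963353,-2.1763662883926775,False,False,False
Infections and infestations,10040047,Sepsis,CDOX,3,10,38,149,1.1763157894736842,0.3084844880638764,4.4855378150442915,1.1634146341463414,0.05665179320467493,0.5858644670155487,-1.6150945005856392,False,False,False
Infections and infestations,10040047,Sepsis,DOXIL,6,7,32,155,4.151785714285714,1.3081492584224275,13.17687909568853,3.654135338345865,6.6612514496931405,1.5028438802476511,-0.4408969211458783,True,True,False
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10051398,Malignant neoplasm progression,CDOX,1,8,40,151,0.471875,0.05733112589374691,3.883859110628177,0.4847560975609756,0.5097374560297678,0.11637918371432851,-2.8633313571596184,False,False,False
"Neoplasms benign, malignant and unspecified (incl cysts and polyps)",10051398,Malignant neoplasm progression,DOXIL,1,8,37,154,0.5202702702702703,0.06310179363432368,4.289595248206471,0.5328947368421053,0.3810940748981022,0.22600367488882675,-2.795846381328565,False,False,False
"Respiratory, thoracic and mediastinal disorders",10035664,Pneumonia,CDOX,4,7,37,152,2.3474903474903477,0.652730546066801,8.442551010928762,2.21602787456446,1.7974026564301144,1.1488006614067061,-1.033683189147507,False,False,False
"Respiratory, thoracic and mediastinal disorders",10035664,Pneumonia,DOXIL,1,10,37,152,0.41081081081081083,0.050975281447657304,3.310732525377588,0.4263157894736842,0.7426597420099695,-0.06350294230615806,-2.9424438332098912,False,False,False
"Respiratory, thoracic and mediastinal disorders",10035664,Pneumonia,MYOCET,2,9,11,178,3.595959595959596,0.6914703655710611,18.700621255250333,3.1965811965811968,2.6137063570218655,2.0689473537174914,-1.2692295494913366,False,False,False
Skin and subcutaneous tissue disorders,10033553,Palmar-plantar erythrodysaesthesia syndrome,CDOX,2,16,39,143,0.4583333333333333,0.1010468089695392,2.078931997820637,0.4847560975609756,1.0698885066119301,-0.2986583155645152,-2.5229005264416404,False,False,False
Skin and subcutaneous tissue disorders,10033553,Palmar-plantar erythrodysaesthesia syndrome,DOXIL,14,4,24,158,23.041666666666668,7.000855800558613,75.83621458613882,14.921052631578947,44.403665066433106,2.1328942704973453,0.6527720922356781,True,True,True
Skin and subcutaneous tissue disorders,10033553,Palmar-plantar erythrodysaesthesia syndrome,MYOCET,1,17,12,170,0.8333333333333334,0.1020434915536293,6.805377137448074,0.8461538461538461,0.029030798261567483,0.7734914701913201,-2.4563986525668864,False,False,False
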