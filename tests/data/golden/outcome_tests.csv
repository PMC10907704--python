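category,group_1,group_2,count_1,total_1,count_2,total_2,test,statistic,p_value,significant
death,CDOX,DOXIL,4,41,6,38,Fisher,0.5765765765765766,0.5085272801428588,False
disability,CDOX,DOXIL,0,41,0,38,Fisher,,1.0,False
hospitalization-initial or prolonged,CDOX,DOXIL,15,41,15,38,chi-square,0.06985014801812899,0.7915550893407958,False
life-threatening,CDOX,DOXIL,3,41,2,38,Fisher,1.4210526315789473,1.0,False
required intervention,CDOX,DOXIL,0,41,0,38,Fisher,,1.0,False
congenital anomaly,CDOX,DOXIL,0,41,0,38,Fisher,,1.0,False
other serious (important medical event),CDOX,DOXIL,19,41,14,38,chi-square,0.7316633432612666,0.39234456498228454,False
death,CDOX,MYOCET,4,41,0,13,Fisher,inf,0.5618037571422698,False
disability,CDOX,MYOCET,0,41,0,13,Fisher,,1.0,False
hospitalization-initial or prolonged,CDOX,MYOCET,15,41,7,13,chi-square,1.2180624253794976,0.2697412372244963,False
life-threatening,CDOX,MYOCET,3,41,1,13,Fisher,0.9473684210526315,1.0,False
required intervention,CDOX,MYOCET,0,41,0,13,Fisher,,1.0,False
congenital anomaly,CDOX,MYOCET,0,41,0,13,Fisher,,1.0,False
other serious (important medical event),CDOX,MYOCET,19,41,5,13,chi-square,0.24821763602251412,0.6183329001964717,False
death,DOXIL,MYOCET,6,38,0,13,Fisher,inf,0.31797977285271184,False
disability,DOXIL,MYOCET,0,38,0,13,Fisher,,1.0,False
hospitalization-initial or prolonged,DOXIL,MYOCET,15,38,7,13,chi-square,0.8157164976584214,0.3664355453867063,False
life-threatening,DOXIL,MYOCET,2,38,1,13,Fisher,0.6666666666666666,1.0,False
required intervention,DOXIL,MYOCET,0,38,0,13,Fisher,,1.0,False
congenital anomaly,DOXIL,MYOCET,0,38,0,13,Fisher,,1.0,False
other serious (important medical event),DOXIL,MYOCET,14,38,5,13,Fisher,0.9333333333333333,1.0,False
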