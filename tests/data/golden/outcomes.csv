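drug_group,total_reports,category,n,pct
CDOX,41,death,4,9.76
CDOX,41,disability,0,0.0
CDOX,41,hospitalization-initial or prolonged,15,36.59
CDOX,41,life-threatening,3,7.32
CDOX,41,required intervention,0,0.0
CDOX,41,congenital anomaly,0,0.0
CDOX,41,other serious (important medical event),19,46.34
CDOX,41,unknown,0,0.0
DOXIL,38,death,6,15.79
DOXIL,38,disability,0,0.0
DOXIL,38,hospitalization-initial or prolonged,15,39.47
DOXIL,38,life-threatening,2,5.26
DOXIL,38,required intervention,0,0.0
DOXIL,38,congenital anomaly,0,0.0
DOXIL,38,other serious (important medical event),14,36.84
DOXIL,38,unknown,1,2.63
MYOCET,13,death,0,0.0
MYOCET,13,disability,0,0.0
MYOCET,13,hospitalization-initial or prolonged,7,53.85
MYOCET,13,life-threatening,1,7.69
MYOCET,13,required intervention,0,0.0
MYOCET,13,congenital anomaly,0,0.0
MYOCET,13,other serious (important medical event),5,38.46
MYOCET,13,unknown,0,0.0
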