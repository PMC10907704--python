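# synthetic synonym dictionary for the three doxorubicin formulation groups
CDOX	CDOX
DOXORUBICIN	CDOX
DOXORUBICIN HCL	CDOX
ADRIAMYCIN	CDOX
DOXIL	DOXIL
CAELYX	DOXIL
DOXORUBICIN HCL LIPOSOME	DOXIL
PEGYLATED LIPOSOMAL DOXORUBICIN	DOXIL
MYOCET	MYOCET
DOXORUBICIN CITRATE LIPOSOME	MYOCET
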