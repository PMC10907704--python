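PRIMARYID,CASEID,FDA_DT,RETAINED_PRIMARYID,REASON
100000001,10000000,20071205,100000002,"same FDA_DT, lesser PRIMARYID than retained version"
100000071,10000007,20061023,100000073,earlier FDA_DT than retained version
100000072,10000007,20070817,100000073,"same FDA_DT, lesser PRIMARYID than retained version"
100000081,10000008,20151214,100000082,"same FDA_DT, lesser PRIMARYID than retained version"
100000201,10000020,20040526,100000203,earlier FDA_DT than retained version
100000202,10000020,20050828,100000203,earlier FDA_DT than retained version
100000261,10000026,20020903,100000263,earlier FDA_DT than retained version
100000262,10000026,20031116,100000263,earlier FDA_DT than retained version
100000281,10000028,20100708,100000283,earlier FDA_DT than retained version
100000282,10000028,20110721,100000283,earlier FDA_DT than retained version
100000301,10000030,20150105,100000303,earlier FDA_DT than retained version
100000302,10000030,20150507,100000303,earlier FDA_DT than retained version
100000401,10000040,20150210,100000403,earlier FDA_DT than retained version
100000402,10000040,20141122,100000403,earlier FDA_DT than retained version
100000421,10000042,20191129,100000422,earlier FDA_DT than retained version
100000461,10000046,20210315,100000462,earlier FDA_DT than retained version
100000471,10000047,20180904,100000473,earlier FDA_DT than retained version
100000472,10000047,20181227,100000473,"same FDA_DT, lesser PRIMARYID than retained version"
100000571,10000057,20061021,100000572,earlier FDA_DT than retained version
100000661,10000066,20030725,100000662,earlier FDA_DT than retained version
100000671,10000067,20070212,100000673,earlier FDA_DT than retained version
100000672,10000067,20080320,100000673,earlier FDA_DT than retained version
100000701,10000070,20081013,100000702,earlier FDA_DT than retained version
100000741,10000074,20110331,100000742,earlier FDA_DT than retained version
100000811,10000081,20200714,100000813,earlier FDA_DT than retained version
100000812,10000081,20201225,100000813,earlier FDA_DT than retained version
100000951,10000095,20060614,100000952,earlier FDA_DT than retained version
100000991,10000099,20110611,100000993,earlier FDA_DT than retained version
100000992,10000099,20120306,100000993,earlier FDA_DT than retained version
100001021,10000102,20150723,100001023,earlier FDA_DT than retained version
100001022,10000102,20161128,100001023,earlier FDA_DT than retained version
100001081,10000108,20151124,100001082,"same FDA_DT, lesser PRIMARYID than retained version"
100001161,10000116,20211119,100001162,earlier FDA_DT than retained version
100001181,10000118,20120314,100001183,earlier FDA_DT than retained version
100001182,10000118,20130628,100001183,earlier FDA_DT than retained version
100001221,10000122,20200127,100001222,"same FDA_DT, lesser PRIMARYID than retained version"
100001291,10000129,20070308,100001293,earlier FDA_DT than retained version
100001292,10000129,20080223,100001293,earlier FDA_DT than retained version
100001341,10000134,20150205,100001342,"same FDA_DT, lesser PRIMARYID than retained version"
100001361,10000136,20050718,100001362,"same FDA_DT, lesser PRIMARYID than retained version"
100001371,10000137,20040407,100001372,"same FDA_DT, lesser PRIMARYID than retained version"
100001491,10000149,20080810,100001493,earlier FDA_DT than retained version
100001492,10000149,20100327,100001493,"same FDA_DT, lesser PRIMARYID than retained version"
100001541,10000154,20040205,100001542,"same FDA_DT, lesser PRIMARYID than retained version"
100001551,10000155,20210313,100001553,earlier FDA_DT than retained version
100001552,10000155,20220620,100001553,earlier FDA_DT than retained version
100001561,10000156,20050127,100001562,earlier FDA_DT than retained version
100001611,10000161,20181119,100001613,earlier FDA_DT than retained version
100001612,10000161,20190517,100001613,earlier FDA_DT than retained version
100001681,10000168,20100917,100001682,earlier FDA_DT than retained version
100001711,10000171,20200714,100001713,earlier FDA_DT than retained version
100001712,10000171,20210611,100001713,earlier FDA_DT than retained version
100001721,10000172,20040614,100001722,earlier FDA_DT than retained version
100001741,10000174,20080801,100001742,earlier FDA_DT than retained version
100001761,10000176,20161216,100001762,"same FDA_DT, lesser PRIMARYID than retained version"
100001771,10000177,20120602,100001773,earlier FDA_DT than retained version
100001772,10000177,20120912,100001773,earlier FDA_DT than retained version
100001791,10000179,20080120,100001793,earlier FDA_DT than retained version
100001792,10000179,20080126,100001793,earlier FDA_DT than retained version
100001901,10000190,20131105,100001903,earlier FDA_DT than retained version
100001902,10000190,20130909,100001903,earlier FDA_DT than retained version
100001991,10000199,20181111,100001992,earlier FDA_DT than retained version
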