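PRIMARYID$CASEID$OUTC_COD
100000001$10000000$DE
100000002$10000000$DE
100000021$10000002$OT
100000041$10000004$HO
100000051$10000005$HO
100000061$10000006$HO
100000081$10000008$HO
100000082$10000008$HO
100000091$10000009$DE
100000101$10000010$OT
100000121$10000012$OT
100000131$10000013$OT
100000141$10000014$OT
100000151$10000015$OT
100000161$10000016$HO
100000171$10000017$HO
100000181$10000018$OT
100000191$10000019$OT
100000201$10000020$LT
100000202$10000020$LT
100000203$10000020$LT
100000211$10000021$OT
100000221$10000022$OT
100000231$10000023$HO
100000241$10000024$OT
100000251$10000025$HO
100000271$10000027$HO
100000281$10000028$OT
100000282$10000028$OT
100000283$10000028$OT
100000301$10000030$HO
100000302$10000030$HO
100000303$10000030$HO
100000321$10000032$DE
100000341$10000034$HO
100000351$10000035$DE
100000361$10000036$OT
100000371$10000037$OT
100000381$10000038$OT
100000391$10000039$OT
100000401$10000040$HO
100000402$10000040$HO
100000403$10000040$HO
100000411$10000041$OT
100000421$10000042$HO
100000422$10000042$HO
100000441$10000044$OT
100000451$10000045$DE
100000461$10000046$HO
100000462$10000046$HO
100000481$10000048$HO
100000491$10000049$HO
100000501$10000050$HO
100000511$10000051$HO
100000521$10000052$LT
100000531$10000053$HO
100000541$10000054$OT
100000551$10000055$LT
100000561$10000056$HO
100000571$10000057$HO
100000572$10000057$HO
100000581$10000058$DE
100000591$10000059$HO
100000611$10000061$DS
100000621$10000062$HO
100000631$10000063$HO
100000641$10000064$OT
100000651$10000065$HO
100000661$10000066$LT
100000662$10000066$LT
100000671$10000067$HO
100000672$10000067$HO
100000673$10000067$HO
100000681$10000068$HO
100000691$10000069$HO
100000701$10000070$OT
100000702$10000070$OT
100000711$10000071$DE
100000721$10000072$OT
100000731$10000073$HO
100000741$10000074$LT
100000742$10000074$LT
100000751$10000075$HO
100000761$10000076$HO
100000781$10000078$OT
100000791$10000079$OT
100000811$10000081$OT
100000812$10000081$OT
100000813$10000081$OT
100000821$10000082$HO
100000831$10000083$OT
100000841$10000084$HO
100000861$10000086$OT
100000871$10000087$HO
100000881$10000088$HO
100000891$10000089$OT
100000901$10000090$OT
100000911$10000091$OT
100000931$10000093$DE
100000941$10000094$OT
100000951$10000095$OT
100000952$10000095$OT
100000961$10000096$OT
100000971$10000097$LT
100000981$10000098$LT
100000991$10000099$DE
100000992$10000099$DE
100000993$10000099$DE
100001001$10000100$HO
100001021$10000102$OT
100001022$10000102$OT
100001023$10000102$OT
100001031$10000103$HO
100001041$10000104$HO
100001051$10000105$HO
100001061$10000106$HO
100001071$10000107$OT
100001091$10000109$OT
100001111$10000111$DE
100001121$10000112$HO
100001131$10000113$OT
100001151$10000115$OT
100001161$10000116$DE
100001162$10000116$DE
100001171$10000117$HO
100001181$10000118$HO
100001182$10000118$HO
100001183$10000118$HO
100001191$10000119$OT
100001201$10000120$HO
100001211$10000121$OT
100001221$10000122$HO
100001222$10000122$HO
100001231$10000123$OT
100001241$10000124$HO
100001251$10000125$OT
100001271$10000127$LT
100001281$10000128$OT
100001291$10000129$HO
100001292$10000129$HO
100001293$10000129$HO
100001301$10000130$OT
100001311$10000131$OT
100001331$10000133$OT
100001341$10000134$LT
100001342$10000134$LT
100001351$10000135$OT
100001361$10000136$OT
100001362$10000136$OT
100001371$10000137$HO
100001372$10000137$HO
100001381$10000138$OT
100001391$10000139$OT
100001401$10000140$HO
100001411$10000141$DE
100001421$10000142$LT
100001431$10000143$HO
100001441$10000144$HO
100001451$10000145$OT
100001471$10000147$DE
100001481$10000148$HO
100001491$10000149$DE
100001492$10000149$DE
100001493$10000149$DE
100001501$10000150$HO
100001511$10000151$OT
100001521$10000152$HO
100001531$10000153$DE
100001541$10000154$OT
100001542$10000154$OT
100001551$10000155$HO
100001552$10000155$HO
100001553$10000155$HO
100001561$10000156$HO
100001562$10000156$HO
100001571$10000157$OT
100001581$10000158$DE
100001601$10000160$HO
100001611$10000161$HO
100001612$10000161$HO
100001613$10000161$HO
100001631$10000163$HO
100001641$10000164$LT
100001651$10000165$OT
100001661$10000166$DE
100001671$10000167$OT
100001691$10000169$HO
100001701$10000170$HO
100001711$10000171$OT
100001712$10000171$OT
100001713$10000171$OT
100001721$10000172$HO
100001722$10000172$HO
100001741$10000174$HO
100001742$10000174$HO
100001751$10000175$HO
100001761$10000176$OT
100001762$10000176$OT
100001771$10000177$HO
100001772$10000177$HO
100001773$10000177$HO
100001781$10000178$OT
100001791$10000179$OT
100001792$10000179$OT
100001793$10000179$OT
100001801$10000180$OT
100001811$10000181$LT
100001821$10000182$HO
100001831$10000183$OT
100001841$10000184$OT
100001851$10000185$HO
100001861$10000186$HO
100001871$10000187$HO
100001891$10000189$HO
100001911$10000191$HO
100001921$10000192$OT
100001931$10000193$OT
100001941$10000194$HO
100001951$10000195$HO
100001961$10000196$HO
100001971$10000197$HO
100001981$10000198$DE
100001991$10000199$DE
100001992$10000199$DE
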