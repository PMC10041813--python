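facility,beds,competing_transfusing,low_level,units_received,units_transfused,market_share_pct,sci
Bungoma County Referral,211,9,14,9543,13679,16.31,0.21
Webuye Hospital,224,11,16,2888,4098,14.17,0.18
Kimilili Subcounty Hospital,81,5,11,503,809,11.27,0.14
Kory Family Hospital Kimilili,75,5,11,244,311,10.44,0.11
Cheptais Sub County Hospital,34,3,5,20,24,7.89,0.10
Lugulu Friends Mission,122,12,16,1135,1254,7.07,0.09
Naitiri Sub County Hospital,40,5,9,229,271,5.57,0.07
Mt Elgon Sub County Hospital,39,5,6,63,49,5.43,0.07
Bumula Sub County Hospital,37,6,8,58,70,4.29,0.06
Nabuala Medical Centre,65,11,14,131,241,4.11,0.05
St Damiano Mission,68,12,16,600,569,3.94,0.05
Sirisia Sub County Hospital,31,6,9,147,138,3.60,0.04
Chwele Sub County Hospital,41,10,11,53,39,2.85,0.03
Lumboka Medical,27,10,15,867,1101,1.88,0.02
Kory Family Hospital Kanduyi,17,10,16,181,190,1.18,0.01
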