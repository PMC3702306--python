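BEGIN IONS
TITLE=fra2_etd_01
PEPMASS=1023.5
CHARGE=2+
955.9 120.0 
1156.1 180.0 
1269.7 460.0 
1534.8 390.0 
1748.6 210.0 
1861.8 160.0 
1932.9 140.0 
END IONS

BEGIN IONS
TITLE=fra2_etd_02
PEPMASS=1023.5
CHARGE=2+
955.4 120.0 
1155.5 180.0 
1269.6 460.0 
1634.7 390.0 
1747.7 210.0 
1860.8 160.0 
1931.8 140.0 
END IONS

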