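cell_line,gene,alteration
BC3C,PIK3CA,GOF
BC3C,TP53,LOF
BFTC905,MYC,GOF
BFTC905,NRAS,GOF
BFTC905,TP53,LOF
CAL29,PIK3CA,GOF
CAL29,RPS6KB2,GOF
CAL29,TP53,LOF
HT1197,NRAS,GOF
HT1197,PIK3CA,GOF
HT1376,CDKN1A,LOF
HT1376,MAPK3,GOF
HT1376,TP53,LOF
J82,FGFR3,GOF
J82,PIK3CA,GOF
J82,TP53,LOF
JMSU1,ATM,LOF
JMSU1,TP53,LOF
KMBC2,CDKN1A,LOF
KMBC2,MAX,LOF
KMBC2,PTEN,LOF
KMBC2,TP53,LOF
KU1919,AKT1,GOF
KU1919,NRAS,GOF
KU1919,RPS6KB2,GOF
RT112,CDKN1A,LOF
RT112,FGFR3,GOF
RT112,PIK3CA,GOF
RT112,TP53,LOF
RT11284,TP53,LOF
SCABER,CDKN2A,LOF
SCABER,TP53,LOF
SW1710,TP53,LOF
T24,HRAS,GOF
T24,TP53,LOF
TCCSUP,PIK3CA,GOF
TCCSUP,TP53,LOF
UMUC1,TP53,LOF
UMUC3,ATM,LOF
UMUC3,KRAS,GOF
UMUC3,TP53,LOF
VMCUB1,CDKN2A,LOF
VMCUB1,MAPK1,GOF
VMCUB1,PIK3CA,GOF
VMCUB1,TP53,LOF
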