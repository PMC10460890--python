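node,node_class,genes,oncokb
ATF2,C0,ATF2,
ATM,C0,ATM,Tumor suppressor
ELK1,C0,ELK1,
FOS,C0,FOS,
FRS2,C0,FRS2,
GAB1,C0,GAB1,Oncogene
GRB2,C0,GRB2,
JUN,C0,JUN,Oncogene
PKC,C0,PRKCA PRKCB PRKCG,
RAF,C0,RAF1 BRAF ARAF,Oncogene
RSK,C0,RPS6KA1 RPS6KA2 RPS6KA3 RPS6KA6,
TAOK,C0,TAOK1 TAOK2 TAOK3,
AKT,C1,AKT1 AKT2 AKT3,Oncogene
AP1,C1,,
BCL2,C1,BCL2,Oncogene
CREB,C1,CREB1,Oncogene
DUSP1,C1,DUSP1,
FGFR3,C1,FGFR3,Oncogene
FOXO3,C1,FOXO3,
MAP3K1_3,C1,MAP3K1 MAP3K2 MAP3K3,Tumor suppressor
MAX,C1,MAX,Tumor suppressor
MSK,C1,RPS6KA4 RPS6KA5,Oncogene
p70,C1,RPS6KB1 RPS6KB2,Oncogene
PDK1,C1,PDK1,
PI3K,C1,PIK3CA,Oncogene
PLCG,C1,PLCG1 PLCG2,Oncogene
PPP2CA,C1,PPP2CA,
PTEN,C1,PTEN,Tumor suppressor
RAS,C1,HRAS KRAS NRAS,Oncogene
SOS,C1,SOS1 SOS2,Oncogene
SPRY,C1,SPRY2,
EGFR,C2,EGFR,Oncogene
ERK,C2,MAPK1 MAPK3,Oncogene
JNK,C2,MAPK8 MAPK9,
MEK1_2,C2,MAP2K1 MAP2K2,Oncogene
GADD45,C3,GADD45A GADD45B GADD45G,
MDM2,C3,MDM2,Oncogene
MTK1,C3,MAP3K4,
MYC,C3,MYC,Oncogene
p14,C3,CDKN2A,Tumor suppressor
p21,C3,CDKN1A,Tumor suppressor
p38,C3,MAPK11 MAPK12 MAPK13 MAPK14,
p53,C3,TP53,Tumor suppressor
SMAD,C3,SMAD2 SMAD3 SMAD4,Tumor suppressor
TAK1,C3,MAP3K7,
TGFBR,C3,TGFBR1 TGFBR2 TGFBR3,Tumor suppressor
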