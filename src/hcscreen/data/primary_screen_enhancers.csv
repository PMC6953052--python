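compound,mean_z,mean_z_dup,pct_positive,pct_positive_dup,fold_change,fold_change_dup
Ro 31-8220,3.19,1.95,95.8,75,3.96,1.27
merbromin,3.17,,95.4,,0.88,
ellipticine,3.17,,95.4,,1.44,
TPEN,3.16,,95.2,,2.2,
MG-132,3.08,,93.9,,2.6,
puromycin,3.07,2.14,93.7,78.2,3.24,1.38
FCCP,3.06,,93.6,,1.28,
prazocin,3.03,,93.1,,1.23,
Ac-Leu-Leu-Nle-CHO,3.03,,93,,3.11,
chelidonine (+),3.03,,93,,3.41,
parbendazole,3.01,,92.7,,6.75,
bafilomycin A1,2.99,,92.4,,0.77,
erbstatin analog,2.99,,92.4,,2.73,
ikarugamycin,2.97,,92.1,,2.48,
manumycin A,2.95,,91.7,,2.09,
nocodazole,2.94,,91.6,,3.77,
colchicine,2.88,,90.6,,4.26,
piperlongumine,2.85,,90.1,,3.43,
mebendazole,2.85,,90,,4.29,
albendazole,2.84,,89.9,,3.34,
taxol (paclitaxel),2.78,2.5,89,84.3,2.04,5.16
podophyllotoxin,2.75,,88.4,,3.9,
"chrysene-1,4-quinone",2.75,,88.3,,3.46,
tyrphostin 9,2.74,1.75,88.2,71.8,1.23,1.23
quinacrine,2.64,,86.6,,1.14,
penitrem A,2.64,,86.6,,1.59,
azacytidine-5,2.61,,86.1,,1.07,
BAPTA-AM,2.55,,85.1,,1.19,
arvanil,2.53,,84.8,,1.39,
vinblastine,2.53,,84.8,,6.44,
thapsigargin,2.53,,84.7,,2.78,
azaguanine-8,2.52,,84.5,,1.31,
latrunculin B,2.49,,84,,3.26,
methiazole,2.46,,83.6,,3.05,
E6 berbamine,2.45,,83.4,,0.84,
scoulerine,2.37,,82.1,,2.28,
Ala-Ala-Phe-CMK (AAF-CMK),2.36,1.9,81.8,74.2,1.05,0.89
ciclopirox ethanolamine,2.3,,80.9,,1.45,
triciribine,2.29,,80.6,,2.68,
actinomycin D,2.28,,80.5,,1.56,
maprotiline,2.24,,79.9,,0.84,
Hoechst 33342,2.19,,79,,2.66,
TLCK,2.17,,78.8,,1.11,
fumagillin,2.16,,78.5,,0.99,
triptolide,2.13,,78.1,,2.17,
disulfiram,2.08,,77.6,,2.21,
AG-879,2.05,1.97,76.7,75.4,2.46,1.64
SKF-96365,2.01,,76,,3.23,
menadione,2,,75.9,,1.08,
shikonin,1.98,,75.5,,0.96,
cytochalasin D,1.96,,75.2,,2.44,
curcumin,1.95,,75,,0.92,
tetrandrine,1.93,1.52,74.6,67.9,0.77,0.85
"camptothecine (S,+)",1.81,,72.8,,4.93,
hycanthone,1.81,,72.8,,1.15,
geldanamycin,1.75,,71.6,,2.56,
5-iodotubercidin,1.74,,71.5,,1.24,
wiskostatin,1.72,,71.1,,0.84,
trichostatin-A,1.7,,70.8,,1.31,
Tosyl-Phe-CMK (TPCK),1.69,,70.8,,2.75,
Z-FA-FMK,1.69,,70.7,,0.94,
DRB (NSC 401575),1.65,,70.1,,1.18,
dilazep,1.64,,69.9,,1.01,
"6-formylindolo [3,2-B] carbazole",1.64,,69.8,,0.96,
CA-074 Me,1.63,1.62,69.8,69.5,0.96,0.9
"2,5-ditertbutylhydroquinone",1.63,,69.6,,1.24,
NapSul-Ile-Trp-CHO,1.6,1.59,69.2,69,1.41,0.9
raloxifene,1.57,,68.8,,0.79,
piceatannol,1.55,,68.3,,0.92,
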