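compound,mean_z,pct_positive,pct_positive_dup,dose_response_tested,fold_change
lovastatin,-2,9,11.6,Yes,0.91
mestranol (ethynylestradiol 3-methyl ether),-1.99,9.2,,Yes,0.87
thonzonium bromide,-1.97,9.5,,No,0.86
20-Carboxy-leukotriene B4,-1.93,10.2,,No,1.02
estrone,-1.9,10.8,,No,0.98
verapamil,-1.89,10.9,,Yes,0.8
fluspirilene,-1.89,11,16.2,Yes,0.81
phenamil,-1.86,11.4,,No,1.01
lidoflazine,-1.85,11.6,,No,0.85
forskolin,-1.83,12,,No,1.06
methoxy-verapamil,-1.82,12,,No,0.84
indirubin-3'-oxime,-1.82,12.1,,Yes,1.08
fluvastatin,-1.81,12.3,,No,0.96
9(E)-Hexadecenoic acid,-1.71,13.9,,No,0.92
clomiphene,-1.68,14.5,,No,1
nicardipine,-1.67,14.6,,Yes,0.9
methyl benzethonium chloride,-1.64,15.2,,No,1.19
benzethonium chloride,-1.63,15.3,,No,1.07
ethaverine,-1.62,15.5,,No,1.1
proadifen,-1.61,15.5,,Yes,0.94
simvastatin,-1.61,15.6,,Yes,1.01
clofazimine,-1.59,16,,No,0.94
butylparaben,-1.54,16.7,,No,0.95
PP1,-1.54,16.8,,No,1.05
budesonide,-1.54,16.8,,Yes,1.14
GBR 12909,-1.54,16.8,,No,0.9
deptropine,-1.54,16.8,,No,0.96
loperamide,-1.52,17.1,,No,0.77
damnacanthal,-1.51,17.3,,No,1.13
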