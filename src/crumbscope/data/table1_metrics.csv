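# Formulation-mean crumb metrics and crust roughness for bran-enriched fried dough/batter.
# bran_type is the bran group (the 0 g control was measured within each group's batch,
# hence its POsox differs slightly between groups). Percentages are of image/sample area;
# fd is the box-counting surface roughness index (dimensionless, 2-3).
bran_type,bran_concentration_g,product_type,poia_pct,posox_pct,porosity_pct,fd
OB,0,batter,19.66,8.67,81.84,2.58
OB,5,batter,16.55,9.47,67.10,2.55
OB,8,batter,16.03,8.80,73.66,2.62
OB,10,batter,14.52,7.47,76.77,2.61
OB,15,batter,18.22,8.60,80.68,2.58
OB,20,batter,14.97,7.87,65.91,2.66
OB,0,dough,8.29,8.20,80.03,2.69
OB,5,dough,5.56,6.67,69.21,2.73
OB,8,dough,14.28,7.13,54.94,2.74
OB,10,dough,11.31,6.33,58.58,2.76
OB,15,dough,18.92,5.27,65.93,2.57
OB,20,dough,11.73,7.53,60.76,2.73
WB,0,batter,19.66,8.53,81.84,2.58
WB,5,batter,13.18,9.93,55.71,2.64
WB,8,batter,13.81,7.67,53.12,2.64
WB,10,batter,16.00,9.87,70.56,2.65
WB,15,batter,13.52,10.13,75.69,2.67
WB,20,batter,15.31,8.73,76.05,2.64
WB,0,dough,8.29,7.07,80.03,2.69
WB,5,dough,4.57,8.00,52.15,2.67
WB,8,dough,9.29,7.73,73.08,2.57
WB,10,dough,6.43,6.07,54.68,2.66
WB,15,dough,7.58,6.20,56.88,2.56
WB,20,dough,7.94,5.00,65.15,2.63
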