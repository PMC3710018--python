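kind,method_a,method_b,printed,consistent
ctax,MTMC,BAT,0.80,True
ctax,MTMC,HW,0.43,False
ctax,MTMC,BSD,0.42,True
ctax,MTMC,GMYC,0.24,True
ctax,MTMC,ITAX,0.72,False
ctax,MTMC,WP,0.67,True
ctax,BAT,HW,0.57,False
ctax,BAT,BSD,0.53,True
ctax,BAT,GMYC,0.30,True
ctax,BAT,ITAX,0.91,True
ctax,BAT,WP,0.57,True
ctax,HW,BSD,0.63,False
ctax,HW,GMYC,0.36,False
ctax,HW,ITAX,0.64,False
ctax,HW,WP,0.33,False
ctax,BSD,GMYC,0.57,False
ctax,BSD,ITAX,0.57,False
ctax,BSD,WP,0.63,True
ctax,GMYC,ITAX,0.33,True
ctax,GMYC,WP,0.36,True
ctax,ITAX,WP,0.53,True
mean_ctax,MTMC,,0.52,False
mean_ctax,BAT,,0.61,True
mean_ctax,HW,,0.49,True
mean_ctax,BSD,,0.56,True
mean_ctax,GMYC,,0.35,False
mean_ctax,ITAX,,0.62,True
mean_ctax,WP,,0.51,False
rtax,MTMC,,0.24,True
rtax,BAT,,0.30,True
rtax,HW,,0.36,True
rtax,BSD,,0.57,False
rtax,GMYC,,1.00,True
rtax,ITAX,,0.33,True
rtax,WP,,0.36,True
nb_species,MTMC,,9,True
nb_species,BAT,,11,True
nb_species,HW,,13,True
nb_species,BSD,,20,True
nb_species,GMYC,,34,True
nb_species,ITAX,,12,True
nb_species,WP,,13,True
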