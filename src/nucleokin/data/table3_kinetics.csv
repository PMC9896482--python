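vessel,volume_ml,impeller_type,impeller_speed_rpm,M,J_per_m3_s,t_g_s,rmse,use_in_ml
EasyMax,85,RC,150,5,1.000,25000,0.16,training and validation
EasyMax,85,RC,225,8,1.600,21000,0.07,training and validation
EasyMax,85,RC,315,14,2.800,14000,0.15,training and validation
EasyMax,85,RC,353,8,1.600,12000,0.09,training and validation
EasyMax,85,RC,365,6,1.800,9800,0.15,training and validation
EasyMax,85,RC,383,7,2.800,11000,0.13,training and validation
EasyMax,85,RC,450,8,0.770,9200,0.14,training and validation
EasyMax,85,PBT,400,11,1.500,4200,0.11,training and validation
EasyMax,85,PBT,330,8,1.300,11000,0.11,training and validation
EasyMax,85,PBT,267,9,0.480,3600,0.13,training and validation
OptiMax,630,RC,300,6,0.180,7000,0.15,training and validation
OptiMax,630,PBT,250,6,0.150,14000,0.13,training and validation
OptiMax,630,PBT,310,7,0.220,3300,0.08,training and validation
Miniplant,9300,RC,165,7,0.034,13000,0.11,training and validation
EasyMax,85,RC,250,9,2.300,18000,0.07,testing
OptiMax,630,RC,220,7,0.120,6500,0.12,testing
Miniplant,9300,RC,300,5,0.084,8600,0.17,testing
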