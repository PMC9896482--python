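scale,vessel_diameter_mm,liquid_height_mm,impeller_type,impeller_diameter_mm,flow
100 mL,51,41.5,RC,30,radial
100 mL,51,41.5,PBT,25,axial
1000 mL,100,81,RC,32,radial
1000 mL,100,81,PBT,45,axial
10 L,200,162,RC,110,radial
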