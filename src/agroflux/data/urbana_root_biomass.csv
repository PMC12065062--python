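crop,depth_top_cm,depth_bottom_cm,root_kg_ha,soil_c_g_kg
corn,0,10,3520,18.44
corn,10,20,200,15.48
corn,20,30,120,14.82
corn,30,60,90,9.46
corn,60,90,110,4.79
switchgrass,0,10,17840,21.56
switchgrass,10,20,1340,14.88
switchgrass,20,30,680,12.73
switchgrass,30,60,2570,7.20
switchgrass,60,90,1090,4.63
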