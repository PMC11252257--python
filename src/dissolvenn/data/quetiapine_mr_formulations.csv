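batch,x1_sodium_citrate_mg,x2_eudragit_L100_55_mg,x3_eudragit_L30_D55_mg,x4_lactose_mg,x5_dcp_mg,x6_glyceryl_behenate_mg
F1,75,10,15,8.5,15.73,40
F2,50,5,15,38.5,15.73,40
F3,50,15,15,28.5,15.73,40
F4,50,10,10,38.5,15.73,40
F5,50,10,15,53.5,15.73,20
F6,50,10,15,13.5,15.73,60
F7,25,0,20,40,48.73,30
F8,25,0,30,40,38.73,30
F9,25,0,30,40,28.73,40
F10,50,0,30,40,3.73,40
F11,50,0,30,20,3.73,60
F12,50,10,10,38,15.73,40
F13,50,10,20,28,15.73,40
F14,45,10,15,33.5,20.73,40
F15,55,10,15,28,15.73,40
F16,45,10,15,39,15.73,40
F17,55,10,15,33.5,10.73,40
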