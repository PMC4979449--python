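case,age,sex,inheritance,AL_mm,VA_logMAR,MD_dB,FS_dB,EZ,enlarged_pct
1,24,M,S,22.3,0.10,-17.47,24.25,Disappeared,3.6
2,24,F,S,24.1,0.00,-15.2,33,Abnormal,6.0
3,31,F,AR,25.2,-0.08,-4.68,35,Normal,5.7
4,40,F,S,23.5,0.00,-11.64,26,Disappeared,4.3
5,31,M,AR,25.2,0.00,-25.59,30.5,Abnormal,4.6
6,23,F,S,25.3,0.22,-23.23,29.75,Disappeared,8.2
7,35,F,S,22.0,-0.08,-17.71,33.5,Abnormal,10.3
8,36,F,S,25.1,-0.08,-1.16,36.2,Normal,3.0
9,35,F,AD,26.5,-0.18,1.67,37.5,Normal,0.5
10,36,F,AD,24.5,0.00,-10.11,34,Abnormal,6.4
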