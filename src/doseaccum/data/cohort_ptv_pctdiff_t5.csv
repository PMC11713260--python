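patient,metric,comparison,value
P1,D90,ecD-pD,0.3
P1,D90,mdD-pD,0.2
P1,D90,mdD-ecD,-0.1
P1,D98,ecD-pD,-2.1
P1,D98,mdD-pD,-0.3
P1,D98,mdD-ecD,1.8
P2,D90,ecD-pD,-0.2
P2,D90,mdD-pD,-0.3
P2,D90,mdD-ecD,-0.1
P2,D98,ecD-pD,-1.2
P2,D98,mdD-pD,-1.0
P2,D98,mdD-ecD,0.1
P3,D90,ecD-pD,-1.9
P3,D90,mdD-pD,-1.7
P3,D90,mdD-ecD,0.2
P3,D98,ecD-pD,-5.2
P3,D98,mdD-pD,-4.0
P3,D98,mdD-ecD,1.3
P4,D90,ecD-pD,0.1
P4,D90,mdD-pD,-0.6
P4,D90,mdD-ecD,-0.7
P4,D98,ecD-pD,-1.0
P4,D98,mdD-pD,-3.9
P4,D98,mdD-ecD,-3.0
P5,D90,ecD-pD,0.7
P5,D90,mdD-pD,-0.8
P5,D90,mdD-ecD,-1.5
P5,D98,ecD-pD,0.1
P5,D98,mdD-pD,-2.5
P5,D98,mdD-ecD,-2.6
P6,D90,ecD-pD,-0.6
P6,D90,mdD-pD,-0.2
P6,D90,mdD-ecD,0.4
P6,D98,ecD-pD,-2.8
P6,D98,mdD-pD,-3.0
P6,D98,mdD-ecD,-0.2
P7,D90,ecD-pD,-0.1
P7,D90,mdD-pD,0.1
P7,D90,mdD-ecD,0.2
P7,D98,ecD-pD,-0.4
P7,D98,mdD-pD,0.1
P7,D98,mdD-ecD,0.5
P8,D90,ecD-pD,-1.3
P8,D90,mdD-pD,-7.1
P8,D90,mdD-ecD,-5.8
P8,D98,ecD-pD,-3.5
P8,D98,mdD-pD,-23.0
P8,D98,mdD-ecD,-20.2
P9,D90,ecD-pD,-0.9
P9,D90,mdD-pD,-0.1
P9,D90,mdD-ecD,0.9
P9,D98,ecD-pD,-4.5
P9,D98,mdD-pD,-2.1
P9,D98,mdD-ecD,2.5
P10,D90,ecD-pD,1.0
P10,D90,mdD-pD,0.1
P10,D90,mdD-ecD,-0.9
P10,D98,ecD-pD,1.3
P10,D98,mdD-pD,-1.1
P10,D98,mdD-ecD,-2.3
P11,D90,ecD-pD,1.9
P11,D90,mdD-pD,-1.2
P11,D90,mdD-ecD,-3.0
P11,D98,ecD-pD,0.8
P11,D98,mdD-pD,-2.6
P11,D98,mdD-ecD,-3.3
P12,D90,ecD-pD,0.7
P12,D90,mdD-pD,-1.3
P12,D90,mdD-ecD,-1.9
P12,D98,ecD-pD,-1.4
P12,D98,mdD-pD,-4.9
P12,D98,mdD-ecD,-3.5
P13,D90,ecD-pD,0.7
P13,D90,mdD-pD,-0.7
P13,D90,mdD-ecD,-1.4
P13,D98,ecD-pD,-0.1
P13,D98,mdD-pD,-2.6
P13,D98,mdD-ecD,-2.5
P14,D90,ecD-pD,-0.5
P14,D90,mdD-pD,-0.9
P14,D90,mdD-ecD,-0.4
P14,D98,ecD-pD,-1.5
P14,D98,mdD-pD,-2.2
P14,D98,mdD-ecD,-0.7
P15,D90,ecD-pD,-0.2
P15,D90,mdD-pD,-0.5
P15,D90,mdD-ecD,-0.3
P15,D98,ecD-pD,-0.4
P15,D98,mdD-pD,-2.8
P15,D98,mdD-ecD,-2.4
P16,D90,ecD-pD,0.7
P16,D90,mdD-pD,-0.5
P16,D90,mdD-ecD,-1.2
P16,D98,ecD-pD,-0.6
P16,D98,mdD-pD,-1.5
P16,D98,mdD-ecD,-1.0
P17,D90,ecD-pD,0.2
P17,D90,mdD-pD,-0.2
P17,D90,mdD-ecD,-0.4
P17,D98,ecD-pD,-1.2
P17,D98,mdD-pD,-1.5
P17,D98,mdD-ecD,-0.3
P18,D90,ecD-pD,1.3
P18,D90,mdD-pD,-0.3
P18,D90,mdD-ecD,-1.6
P18,D98,ecD-pD,1.3
P18,D98,mdD-pD,-1.0
P18,D98,mdD-ecD,-2.3
P19,D90,ecD-pD,0.8
P19,D90,mdD-pD,0.0
P19,D90,mdD-ecD,-0.8
P19,D98,ecD-pD,-0.6
P19,D98,mdD-pD,-0.5
P19,D98,mdD-ecD,0.1
P20,D90,ecD-pD,-0.1
P20,D90,mdD-pD,-0.6
P20,D90,mdD-ecD,-0.5
P20,D98,ecD-pD,-3.6
P20,D98,mdD-pD,-3.8
P20,D98,mdD-ecD,-0.2
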