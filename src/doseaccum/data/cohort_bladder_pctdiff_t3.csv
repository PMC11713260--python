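patient,metric,comparison,value
P1,D2cc,ecD-pD,4.5
P1,D2cc,mdD-pD,0.9
P1,D2cc,mdD-ecD,-3.6
P1,Dmax,ecD-pD,11.3
P1,Dmax,mdD-pD,3.2
P1,Dmax,mdD-ecD,-6.6
P1,Dmean,ecD-pD,0.6
P1,Dmean,mdD-pD,8.8
P1,Dmean,mdD-ecD,-0.7
P1,V45,ecD-pD,129.0
P1,V45,mdD-pD,123.6
P1,V45,mdD-ecD,-2.4
P2,D2cc,ecD-pD,4.0
P2,D2cc,mdD-pD,-0.2
P2,D2cc,mdD-ecD,-3.9
P2,Dmax,ecD-pD,3.1
P2,Dmax,mdD-pD,-0.9
P2,Dmax,mdD-ecD,-4.1
P2,Dmean,ecD-pD,4.0
P2,Dmean,mdD-pD,9.8
P2,Dmean,mdD-ecD,-3.7
P2,V45,ecD-pD,189.3
P2,V45,mdD-pD,190.2
P2,V45,mdD-ecD,0.3
P3,D2cc,ecD-pD,1.1
P3,D2cc,mdD-pD,0.3
P3,D2cc,mdD-ecD,-0.8
P3,Dmax,ecD-pD,0.7
P3,Dmax,mdD-pD,0.1
P3,Dmax,mdD-ecD,-0.6
P3,Dmean,ecD-pD,1.1
P3,Dmean,mdD-pD,0.2
P3,Dmean,mdD-ecD,-0.9
P3,V45,ecD-pD,65.9
P3,V45,mdD-pD,62.1
P3,V45,mdD-ecD,-2.3
P4,D2cc,ecD-pD,-4.6
P4,D2cc,mdD-pD,-2.2
P4,D2cc,mdD-ecD,2.5
P4,Dmax,ecD-pD,-0.9
P4,Dmax,mdD-pD,-0.5
P4,Dmax,mdD-ecD,0.5
P4,Dmean,ecD-pD,-0.6
P4,Dmean,mdD-pD,-1.2
P4,Dmean,mdD-ecD,-0.7
P4,V45,ecD-pD,-16.3
P4,V45,mdD-pD,-21.4
P4,V45,mdD-ecD,-6.2
P5,D2cc,ecD-pD,0.1
P5,D2cc,mdD-pD,-0.7
P5,D2cc,mdD-ecD,-0.6
P5,Dmax,ecD-pD,-1.9
P5,Dmax,mdD-pD,0.6
P5,Dmax,mdD-ecD,2.6
P5,Dmean,ecD-pD,0.2
P5,Dmean,mdD-pD,-0.3
P5,Dmean,mdD-ecD,-0.5
P5,V45,ecD-pD,-65.5
P5,V45,mdD-pD,-66.3
P5,V45,mdD-ecD,-2.5
P6,D2cc,ecD-pD,15.3
P6,D2cc,mdD-pD,9.3
P6,D2cc,mdD-ecD,-5.2
P6,Dmax,ecD-pD,7.2
P6,Dmax,mdD-pD,5.9
P6,Dmax,mdD-ecD,-1.3
P6,Dmean,ecD-pD,4.8
P6,Dmean,mdD-pD,2.7
P6,Dmean,mdD-ecD,-2.1
P6,V45,ecD-pD,63.5
P6,V45,mdD-pD,58.6
P6,V45,mdD-ecD,2.4
P7,D2cc,ecD-pD,-0.1
P7,D2cc,mdD-pD,-0.6
P7,D2cc,mdD-ecD,-0.5
P7,Dmax,ecD-pD,4.0
P7,Dmax,mdD-pD,-0.7
P7,Dmax,mdD-ecD,-4.5
P7,Dmean,ecD-pD,-0.1
P7,Dmean,mdD-pD,-0.2
P7,Dmean,mdD-ecD,-0.2
P7,V45,ecD-pD,-14.3
P7,V45,mdD-pD,-12.2
P7,V45,mdD-ecD,2.4
P8,D2cc,ecD-pD,0.3
P8,D2cc,mdD-pD,0.2
P8,D2cc,mdD-ecD,-0.1
P8,Dmax,ecD-pD,-0.4
P8,Dmax,mdD-pD,-0.5
P8,Dmax,mdD-ecD,-0.1
P8,Dmean,ecD-pD,3.2
P8,Dmean,mdD-pD,0.6
P8,Dmean,mdD-ecD,-2.6
P8,V45,ecD-pD,-24.0
P8,V45,mdD-pD,-42.8
P8,V45,mdD-ecD,-24.7
P9,D2cc,ecD-pD,-0.2
P9,D2cc,mdD-pD,-0.7
P9,D2cc,mdD-ecD,-0.5
P9,Dmax,ecD-pD,-0.6
P9,Dmax,mdD-pD,-1.2
P9,Dmax,mdD-ecD,-0.7
P9,Dmean,ecD-pD,0.0
P9,Dmean,mdD-pD,-0.7
P9,Dmean,mdD-ecD,-0.7
P9,V45,ecD-pD,-34.5
P9,V45,mdD-pD,-33.4
P9,V45,mdD-ecD,1.7
P10,D2cc,ecD-pD,-1.1
P10,D2cc,mdD-pD,-2.4
P10,D2cc,mdD-ecD,-1.4
P10,Dmax,ecD-pD,1.2
P10,Dmax,mdD-pD,-0.4
P10,Dmax,mdD-ecD,-1.5
P10,Dmean,ecD-pD,0.7
P10,Dmean,mdD-pD,-0.9
P10,Dmean,mdD-ecD,-1.6
P10,V45,ecD-pD,17.1
P10,V45,mdD-pD,17.1
P10,V45,mdD-ecD,0.0
P11,D2cc,ecD-pD,2.4
P11,D2cc,mdD-pD,-2.0
P11,D2cc,mdD-ecD,-4.3
P11,Dmax,ecD-pD,2.6
P11,Dmax,mdD-pD,-1.5
P11,Dmax,mdD-ecD,-4.0
P11,Dmean,ecD-pD,2.0
P11,Dmean,mdD-pD,-2.4
P11,Dmean,mdD-ecD,-4.3
P11,V45,ecD-pD,-4.8
P11,V45,mdD-pD,-81.2
P11,V45,mdD-ecD,-80.3
P12,D2cc,ecD-pD,1.3
P12,D2cc,mdD-pD,-0.5
P12,D2cc,mdD-ecD,-1.8
P12,Dmax,ecD-pD,1.1
P12,Dmax,mdD-pD,-0.5
P12,Dmax,mdD-ecD,-1.6
P12,Dmean,ecD-pD,6.4
P12,Dmean,mdD-pD,3.0
P12,Dmean,mdD-ecD,-3.2
P12,V45,ecD-pD,-5.7
P12,V45,mdD-pD,-15.0
P12,V45,mdD-ecD,-9.8
P13,D2cc,ecD-pD,1.7
P13,D2cc,mdD-pD,0.1
P13,D2cc,mdD-ecD,-1.6
P13,Dmax,ecD-pD,1.5
P13,Dmax,mdD-pD,-0.1
P13,Dmax,mdD-ecD,-1.6
P13,Dmean,ecD-pD,2.8
P13,Dmean,mdD-pD,-0.7
P13,Dmean,mdD-ecD,-3.4
P13,V45,ecD-pD,-116.9
P13,V45,mdD-pD,70.6
P13,V45,mdD-ecD,-21.4
P14,D2cc,ecD-pD,-0.2
P14,D2cc,mdD-pD,-0.4
P14,D2cc,mdD-ecD,-0.2
P14,Dmax,ecD-pD,-0.2
P14,Dmax,mdD-pD,-0.8
P14,Dmax,mdD-ecD,-0.6
P14,Dmean,ecD-pD,-13.2
P14,Dmean,mdD-pD,-14.5
P14,Dmean,mdD-ecD,-1.6
P14,V45,ecD-pD,-47.9
P14,V45,mdD-pD,-52.4
P14,V45,mdD-ecD,-8.7
P15,D2cc,ecD-pD,3.9
P15,D2cc,mdD-pD,3.6
P15,D2cc,mdD-ecD,-0.2
P15,Dmax,ecD-pD,1.4
P15,Dmax,mdD-pD,0.9
P15,Dmax,mdD-ecD,-0.5
P15,Dmean,ecD-pD,1.6
P15,Dmean,mdD-pD,1.2
P15,Dmean,mdD-ecD,-0.5
P15,V45,ecD-pD,49.6
P15,V45,mdD-pD,49.3
P15,V45,mdD-ecD,-0.2
P16,D2cc,ecD-pD,1.9
P16,D2cc,mdD-pD,0.1
P16,D2cc,mdD-ecD,-1.8
P16,Dmax,ecD-pD,1.8
P16,Dmax,mdD-pD,0.0
P16,Dmax,mdD-ecD,-1.8
P16,Dmean,ecD-pD,1.6
P16,Dmean,mdD-pD,-1.4
P16,Dmean,mdD-ecD,-2.9
P16,V45,ecD-pD,61.9
P16,V45,mdD-pD,48.1
P16,V45,mdD-ecD,-8.5
P17,D2cc,ecD-pD,4.5
P17,D2cc,mdD-pD,0.9
P17,D2cc,mdD-ecD,-3.5
P17,Dmax,ecD-pD,13.9
P17,Dmax,mdD-pD,11.4
P17,Dmax,mdD-ecD,-2.2
P17,Dmean,ecD-pD,1.8
P17,Dmean,mdD-pD,0.8
P17,Dmean,mdD-ecD,-1.0
P17,V45,ecD-pD,16.3
P17,V45,mdD-pD,16.3
P17,V45,mdD-ecD,0.0
P18,D2cc,ecD-pD,1.0
P18,D2cc,mdD-pD,-0.5
P18,D2cc,mdD-ecD,-1.5
P18,Dmax,ecD-pD,2.4
P18,Dmax,mdD-pD,0.0
P18,Dmax,mdD-ecD,-2.4
P18,Dmean,ecD-pD,3.5
P18,Dmean,mdD-pD,1.3
P18,Dmean,mdD-ecD,-2.1
P18,V45,ecD-pD,-48.2
P18,V45,mdD-pD,-53.3
P18,V45,mdD-ecD,-9.8
P19,D2cc,ecD-pD,2.5
P19,D2cc,mdD-pD,-0.2
P19,D2cc,mdD-ecD,-2.6
P19,Dmax,ecD-pD,2.4
P19,Dmax,mdD-pD,-0.3
P19,Dmax,mdD-ecD,-2.7
P19,Dmean,ecD-pD,3.5
P19,Dmean,mdD-pD,-0.8
P19,Dmean,mdD-ecD,-4.1
P19,V45,ecD-pD,1.0
P19,V45,mdD-pD,-14.3
P19,V45,mdD-ecD,-15.2
P20,D2cc,ecD-pD,0.7
P20,D2cc,mdD-pD,-0.4
P20,D2cc,mdD-ecD,-1.1
P20,Dmax,ecD-pD,0.7
P20,Dmax,mdD-pD,-0.5
P20,Dmax,mdD-ecD,-1.1
P20,Dmean,ecD-pD,1.0
P20,Dmean,mdD-pD,-0.4
P20,Dmean,mdD-ecD,-1.4
P20,V45,ecD-pD,-21.1
P20,V45,mdD-pD,-27.7
P20,V45,mdD-ecD,-8.3
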