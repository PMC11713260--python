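patient,structure,comparison,pass_rate
P1,bladder,pD-ecD,98.0
P1,rectum,pD-ecD,99.0
P1,bladder,pD-mdD,99.0
P1,rectum,pD-mdD,93.0
P2,bladder,pD-ecD,100.0
P2,rectum,pD-ecD,100.0
P2,bladder,pD-mdD,100.0
P2,rectum,pD-mdD,85.0
P3,bladder,pD-ecD,99.0
P3,rectum,pD-ecD,91.0
P3,bladder,pD-mdD,98.0
P3,rectum,pD-mdD,96.0
P4,bladder,pD-ecD,100.0
P4,rectum,pD-ecD,85.0
P4,bladder,pD-mdD,100.0
P4,rectum,pD-mdD,56.0
P5,bladder,pD-ecD,100.0
P5,rectum,pD-ecD,100.0
P5,bladder,pD-mdD,100.0
P5,rectum,pD-mdD,100.0
P6,bladder,pD-ecD,95.0
P6,rectum,pD-ecD,94.0
P6,bladder,pD-mdD,79.0
P6,rectum,pD-mdD,70.0
P7,bladder,pD-ecD,96.0
P7,rectum,pD-ecD,93.0
P7,bladder,pD-mdD,100.0
P7,rectum,pD-mdD,99.0
P8,bladder,pD-ecD,100.0
P8,rectum,pD-ecD,89.0
P8,bladder,pD-mdD,62.0
P8,rectum,pD-mdD,91.0
P9,bladder,pD-ecD,96.0
P9,rectum,pD-ecD,98.0
P9,bladder,pD-mdD,86.0
P9,rectum,pD-mdD,96.0
P10,bladder,pD-ecD,98.0
P10,rectum,pD-ecD,80.0
P10,bladder,pD-mdD,100.0
P10,rectum,pD-mdD,84.0
P11,bladder,pD-ecD,39.0
P11,rectum,pD-ecD,80.0
P11,bladder,pD-mdD,100.0
P11,rectum,pD-mdD,88.0
P12,bladder,pD-ecD,73.0
P12,rectum,pD-ecD,97.0
P12,bladder,pD-mdD,100.0
P12,rectum,pD-mdD,53.0
P13,bladder,pD-ecD,97.0
P13,rectum,pD-ecD,92.0
P13,bladder,pD-mdD,81.0
P13,rectum,pD-mdD,94.0
P14,bladder,pD-ecD,96.0
P14,rectum,pD-ecD,95.0
P14,bladder,pD-mdD,97.0
P14,rectum,pD-mdD,99.0
P15,bladder,pD-ecD,100.0
P15,rectum,pD-ecD,100.0
P15,bladder,pD-mdD,99.0
P15,rectum,pD-mdD,77.0
P16,bladder,pD-ecD,98.0
P16,rectum,pD-ecD,96.0
P16,bladder,pD-mdD,83.0
P16,rectum,pD-mdD,99.0
P17,bladder,pD-ecD,99.0
P17,rectum,pD-ecD,99.0
P17,bladder,pD-mdD,97.0
P17,rectum,pD-mdD,80.0
P18,bladder,pD-ecD,89.0
P18,rectum,pD-ecD,98.0
P18,bladder,pD-mdD,99.0
P18,rectum,pD-mdD,79.0
P19,bladder,pD-ecD,97.0
P19,rectum,pD-ecD,99.0
P19,bladder,pD-mdD,95.0
P19,rectum,pD-mdD,96.0
P20,bladder,pD-ecD,100.0
P20,rectum,pD-ecD,99.0
P20,bladder,pD-mdD,84.0
P20,rectum,pD-mdD,60.0
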