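patient,material,image,mean,sd
P1,bladder,pCT,11.4,7.0
P1,muscle,pCT,46.9,7.6
P1,fat,pCT,-97.9,15.1
P1,cortical,pCT,851.0,158.0
P1,trabecular,pCT,143.1,46.6
P1,bladder,mCBCT,2.0,8.8
P1,muscle,mCBCT,33.8,11.1
P1,fat,mCBCT,-118.1,10.8
P1,cortical,mCBCT,818.7,129.7
P1,trabecular,mCBCT,146.8,42.7
P1,bladder,Enhanced,16.3,7.3
P1,muscle,Enhanced,26.0,8.3
P1,fat,Enhanced,22.1,10.7
P1,cortical,Enhanced,758.1,225.8
P1,trabecular,Enhanced,4.9,34.3
P3,bladder,pCT,8.4,16.0
P3,muscle,pCT,54.5,14.8
P3,fat,pCT,-95.9,13.6
P3,cortical,pCT,968.8,128.1
P3,trabecular,pCT,146.0,41.8
P3,bladder,mCBCT,3.2,12.5
P3,muscle,mCBCT,15.0,9.9
P3,fat,mCBCT,-98.0,11.1
P3,cortical,mCBCT,951.2,137.2
P3,trabecular,mCBCT,128.6,23.4
P3,bladder,Enhanced,21.0,7.8
P3,muscle,Enhanced,46.8,10.5
P3,fat,Enhanced,28.1,14.8
P3,cortical,Enhanced,742.2,102.4
P3,trabecular,Enhanced,232.3,48.0
P9,bladder,pCT,24.3,13.4
P9,muscle,pCT,54.2,14.2
P9,fat,pCT,-97.4,16.3
P9,cortical,pCT,666.2,112.0
P9,trabecular,pCT,134.2,98.2
P9,bladder,mCBCT,24.2,17.6
P9,muscle,mCBCT,33.3,15.9
P9,fat,mCBCT,-96.6,7.6
P9,cortical,mCBCT,614.0,164.5
P9,trabecular,mCBCT,101.7,60.3
P9,bladder,Enhanced,41.5,11.6
P9,muscle,Enhanced,20.5,14.4
P9,fat,Enhanced,21.1,11.7
P9,cortical,Enhanced,405.6,97.0
P9,trabecular,Enhanced,26.1,80.9
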