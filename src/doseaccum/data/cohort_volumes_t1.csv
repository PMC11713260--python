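patient,organ,pct_cc,w1,w2,w3,w4,w5,median
P1,bladder,89.0,227.0,217.0,212.0,-94.0,148.0,212.0
P1,rectum,70.0,110.0,-98.0,-100.0,103.0,111.0,103.0
P2,bladder,28.0,288.0,349.0,107.0,102.0,104.0,107.0
P2,rectum,90.0,-54.0,-55.0,-65.0,-51.0,-75.0,-55.0
P3,bladder,59.0,164.0,-73.0,-62.0,-72.0,137.0,-62.0
P3,rectum,62.0,-91.0,-89.0,107.0,-92.0,119.0,-89.0
P4,bladder,141.0,-87.0,-109.0,-97.0,-92.0,-50.0,-92.0
P4,rectum,101.0,-82.0,-98.0,-87.0,101.0,-84.0,-84.0
P5,bladder,149.0,-36.0,30.0,-34.0,-47.0,-42.0,-36.0
P5,rectum,51.0,106.0,-86.0,-96.0,-93.0,-97.0,-93.0
P6,bladder,68.0,145.0,94.0,-93.0,-66.0,117.0,94.0
P6,rectum,83.0,-60.0,-58.0,112.0,-69.0,144.0,-58.0
P7,bladder,131.0,-88.0,132.0,-54.0,-49.0,-37.0,-49.0
P7,rectum,43.0,-95.0,-92.0,143.0,113.0,106.0,106.0
P8,bladder,48.0,-58.0,-76.0,-95.0,133.0,-96.0,-76.0
P8,rectum,175.0,-59.0,-47.0,-58.0,-56.0,-56.0,-56.0
P9,bladder,152.0,-69.0,-57.0,-71.0,-62.0,-98.0,-69.0
P9,rectum,59.0,123.0,124.0,-92.0,112.0,137.0,123.0
P10,bladder,41.0,117.0,110.0,-64.0,120.0,228.0,117.0
P10,rectum,42.0,129.0,107.0,-91.0,106.0,111.0,107.0
P11,bladder,119.0,-43.0,-96.0,-28.0,-35.0,-73.0,-43.0
P11,rectum,109.0,-77.0,-78.0,-50.0,-54.0,-76.0,-76.0
P12,bladder,80.0,-70.0,-99.0,-92.0,115.0,123.0,-70.0
P12,rectum,116.0,-57.0,-63.0,-73.0,-81.0,101.0,-63.0
P13,bladder,83.0,176.0,163.0,113.0,199.0,-92.0,163.0
P13,rectum,138.0,-66.0,-79.0,-67.0,-84.0,-92.0,-79.0
P14,bladder,136.0,-62.0,-39.0,-80.0,344.0,-88.0,-62.0
P14,rectum,69.0,-97.0,-74.0,-86.0,102.0,-74.0,-74.0
P15,bladder,103.0,148.0,221.0,-56.0,139.0,-42.0,139.0
P15,rectum,99.0,-70.0,123.0,144.0,-99.0,114.0,114.0
P16,bladder,96.0,159.0,-65.0,-59.0,-64.0,113.0,-59.0
P16,rectum,75.0,135.0,166.0,147.0,176.0,109.0,147.0
P17,bladder,27.0,115.0,189.0,123.0,174.0,121.0,123.0
P17,rectum,106.0,-51.0,-67.0,-59.0,-83.0,-76.0,-67.0
P18,bladder,320.0,-39.0,-46.0,-20.0,-28.0,-18.0,-28.0
P18,rectum,59.0,-88.0,105.0,100.0,-93.0,147.0,100.0
P19,bladder,172.0,-89.0,-27.0,-31.0,-30.0,-33.0,-31.0
P19,rectum,57.0,129.0,-98.0,123.0,-80.0,-96.0,-80.0
P20,bladder,114.0,-74.0,-69.0,-84.0,-68.0,-69.0,-69.0
P20,rectum,177.0,-60.0,-67.0,-67.0,-74.0,-84.0,-67.0
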