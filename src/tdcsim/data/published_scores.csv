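Setup,Score,Alpha1,Alpha2,TotalPower,PeakFreq,PLI,AEC
PO7a-AF4c,6,1,1,1,1,1,1
PO8a-AF3c,6,1,1,1,1,1,1
F7a-F4c,6,1,1,1,1,1,1
F8a-F3c,6,1,1,1,1,1,1
P5a-P6c,6,1,1,1,1,1,1
P6a-P5c,6,1,1,1,1,1,1
O1a-F3c,4,1,1,1,1,0,0
O2a-F4c,4,0,1,1,1,0,1
FC5a-FC6c,1,-1,1,1,0,0,0
FT10a-FC3c,1,0,0,1,1,-1,0
F4a-O2c,1,0,0,1,0,0,0
F3a-F8c,-1,-1,1,1,-1,-1,0
FC4a-FT9c,-1,0,0,0,0,-1,0
FC3a-FT10c,-1,0,0,0,0,-1,0
FC6a-FC5c,-2,-1,0,1,0,-1,-1
F3a-O1c,-2,-1,0,0,1,-1,-1
F4a-F7c,-3,-1,0,1,-1,-1,-1
FT9a-FC4c,-3,-1,-1,0,1,-1,-1
AF4a-PO7c,-6,-1,-1,-1,-1,-1,-1
AF3a-PO8c,-6,-1,-1,-1,-1,-1,-1
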