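# Published closed-loop RT delay benchmarks (ms), device minus RT-box reference.
# G = gaming mouse; S1/S2 = standard mice. Sorted ascending by mean delay.
device,n,min,mean,max,sd
PVT-192,211,1.7,3.4,7.6,0.8
Lenovo X230 (G),211,1.8,5.3,9.1,1.6
Dell Dimension 9150 (G),208,1.6,7.8,13.4,2.1
Dell Precision M4500 (G),211,5.4,7.8,10.5,1.0
Dell Dimension 5150 (G),213,2.9,7.9,15.2,1.9
Dell OptiPlex 745 (G),214,2.2,9.1,14.0,2.2
Dell OptiPlex 755 (G),214,4.9,9.3,14.0,1.6
Lenovo X230 (S1),213,21.8,30.8,38.7,3.1
Dell Precision M4500 (S2),213,29.4,35.7,42.9,2.6
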