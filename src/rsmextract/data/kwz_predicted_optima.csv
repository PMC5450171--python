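response,ethanol,temperature,ratio,time,predicted
yield,48.80,74.29,25.09,3.04,40.84
tpc,50.11,72.06,22.73,2.93,48.44
ptp1b,52.10,73.80,21.84,2.95,86.21
aglu,47.57,69.74,22.22,3.03,96.56
abts,52.70,71.50,22.38,3.01,77.68
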