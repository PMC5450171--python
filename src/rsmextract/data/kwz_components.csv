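peak,t_r_min,component,slope,intercept,r2,content_pct,range_low_ugml,range_high_ugml
1,2.4,Gallic acid,6649.1,-625.98,0.9999,0.15,10.0,70.0
2,10.5,Catechin,558.67,3342.2,0.9999,3.63,20.0,1100.0
3,13.0,Chlorogenic acid,4932.2,-11477,1.0000,0.48,57.5,287.0
4,16.8,Epicatechin,708.8,2911.6,0.9999,0.36,45.0,225.0
5,18.2,Corilagin,3623.1,1735.8,1.0000,1.97,130.0,650.0
6,40.9,Ellagic acid,21560,-345092,0.9965,0.45,65.0,228.0
7,53.3,Hyperoside,7500.7,2857.1,1.0000,1.11,55.0,330.0
8,53.9,Rutin,7143.9,4530.4,0.9999,1.11,57.5,345.0
9,54.8,Isoquercitrin,9655.1,-12230,1.0000,0.87,44.0,308.0
10,59.8,Avicularin,12645,-11462,0.9995,0.22,30.0,150.0
11,63.9,Quercitrin,16511,-20026,0.9998,0.31,30.0,150.0
12,80.9,Quercetin,2568.9,-12928,0.9992,0.51,45.0,225.0
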