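# Per-dataset skewness and excess kurtosis of the effective-diameter
# distributions, transcribed from the published study (paper-derived
# reference values, not outputs of this package).
dataset,skewness,excess_kurtosis
SR1-1692,0.146,-0.347
AC1547,0.032,-0.295
A2661-R,0.216,0.246
A2661-L,0.225,-0.317
F-1768,0.074,-0.326
8067-R,0.060,-0.166
8066-R,0.292,-0.176
8066-L,0.198,0.243
8034-L,0.332,-0.162
8036-L,0.234,0.015
8035-L,-0.068,0.072
8034-R,0.175,-0.137
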