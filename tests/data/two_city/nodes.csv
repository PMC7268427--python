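id,lat,lon
s,62.0,26.0
s1,62.02,26.0
s2,61.98,26.0
l,62.0,26.3
l1,62.02,26.3
c1,62.0,26.65
c2,62.0,27.3
c3,62.0,27.7
t,62.0,28.0
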