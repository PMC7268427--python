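u,v,length_km,speed_kmh
s,s1,2.5,50
s,s2,2.5,50
s,l,20,60
l,l1,2.5,50
l,c1,30,90
c1,c2,50,100
c2,c3,30,90
c3,t,20,80
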