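id,lat,lon,area_type,response_min
m1,62.0,26.0,core_urban,10
m2,62.02,26.0,other_urban,5
m3,62.0,27.3,dispersed_settlement,15
m4,62.0,27.7,other_rural,25
m5,62.02,26.3,core_urban,8
m6,62.0,28.0,other_urban,12
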