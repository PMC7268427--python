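stratum,n,heli_faster_n,heli_faster_pct,saved_median,saved_lower,saved_upper,saved_gt30_n,saved_gt30_pct
core_urban,2,2,100.0,50.86233215651446,46.43108522491969,55.29357908810923,2,100.0
other_urban,2,1,50.0,57.929689990107505,57.929689990107505,57.929689990107505,1,50.0
dispersed_settlement,1,1,100.0,9.52603341343918,9.52603341343918,9.52603341343918,0,0.0
other_rural,1,0,0.0,,,,0,0.0
Total,6,4,66.66666666666667,50.86233215651446,12.276420535096555,57.7494734366613,3,50.0
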