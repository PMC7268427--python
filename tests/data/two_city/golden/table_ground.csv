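stratum,n,lysis_median,lysis_lower,lysis_upper,thrombectomy_median,thrombectomy_lower,thrombectomy_upper,increase_n,increase_pct,increase_median,increase_lower,increase_upper
core_urban,2,54.2,46.79,61.61,122.2,114.79,129.61,2,100.0,68.0,68.0,68.0
other_urban,2,53.7,48.285,59.115,87.7,49.985,125.415,1,50.0,68.0,68.0,68.0
dispersed_settlement,1,79.0,79.0,79.0,79.0,79.0,79.0,0,0.0,,,
other_rural,1,73.0,73.0,73.0,73.0,73.0,73.0,0,0.0,,,
Total,6,60.7,46.6,78.25,96.7,51.125,129.675,3,50.0,68.0,68.0,68.0
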