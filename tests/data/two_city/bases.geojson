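{
 "type": "FeatureCollection",
 "features": [
  {"type": "Feature", "properties": {"id": "B1"},
   "geometry": {"type": "Point", "coordinates": [26.0, 62.0]}}
 ]
}
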