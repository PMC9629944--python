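cultivar,brix,moisture_percent
Burlat,24.0,84.01
Van,24.5,86.11
Napoleon,23.1,77.8
Cerisette,17.7,84.56
Coeur pigeon,19.8,82.61
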