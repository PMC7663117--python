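sex,age_lo,age_hi,carbohydrates,fibre,lipids,omega6,omega3,protein,energy
men,9,13,0.910,0.217,0.389,0.084,0.008,0.238,17500
men,14,18,0.910,0.266,0.529,0.112,0.011,0.364,23800
men,19,30,0.910,0.266,0.436,0.119,0.011,0.392,19600
men,31,50,0.910,0.266,0.389,0.119,0.011,0.392,17500
men,51,70,0.910,0.210,0.319,0.098,0.011,0.392,14350
men,71,75,0.910,0.210,0.311,0.098,0.011,0.392,14000
women,9,13,0.910,0.182,0.342,0.070,0.007,0.238,15400
women,14,18,0.910,0.182,0.389,0.077,0.008,0.322,17500
women,19,30,0.910,0.175,0.342,0.084,0.008,0.322,15400
women,31,50,0.910,0.175,0.303,0.084,0.008,0.322,13650
women,51,70,0.910,0.147,0.272,0.077,0.008,0.322,12250
women,71,75,0.910,0.147,0.264,0.077,0.008,0.322,11900
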