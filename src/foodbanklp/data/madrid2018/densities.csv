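food_group,carbohydrates,fibre,lipids,omega6,omega3,protein,water,energy
cereal,591.568,33.017,52.669,7.102,0.444,84.367,238.379,3231.424
vegetables,85.626,18.125,2.778,0.228,0.099,17.024,876.447,438.705
fruit,129.716,18.594,12.380,1.362,0.125,12.063,827.248,732.678
fats_and_oils,0.713,0.000,967.151,83.183,3.791,0.860,31.276,8557.613
dairy,64.445,0.178,36.964,3.897,0.598,44.913,853.500,750.534
fish,2.745,0.000,69.556,23.223,7.117,167.528,760.171,1359.269
meat,3.846,0.000,121.615,29.703,3.442,170.717,703.822,1897.343
eggs,0.000,0.000,102.321,8.161,0.770,121.487,776.192,1387.487
pulses,435.433,86.444,27.740,4.425,0.038,179.292,271.091,2952.075
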