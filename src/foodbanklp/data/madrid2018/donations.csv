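food_group,donation
cereal,51667
vegetables,68820
fruit,93989
fats_and_oils,12519
dairy,72742
fish,5790
meat,3712
eggs,0
pulses,13178
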