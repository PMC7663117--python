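food_group,price
cereal,2.70
vegetables,1.19
fruit,1.01
fats_and_oils,3.17
dairy,2.40
fish,3.18
meat,3.18
eggs,2.00
pulses,2.90
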