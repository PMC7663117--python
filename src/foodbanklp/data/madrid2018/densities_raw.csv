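food_group,carbohydrates,fibre,lipids,omega6,omega3,protein,water,energy
cereal,577.618,32.239,51.427,6.935,0.433,82.377,232.758,3155.225
vegetables,81.235,17.195,2.636,0.216,0.094,16.151,831.503,416.208
fruit,107.254,15.374,10.236,1.126,0.104,9.974,684.000,605.806
fats_and_oils,0.725,0.000,983.234,84.566,3.854,0.874,31.796,8699.919
dairy,69.209,0.192,39.697,4.185,0.642,48.233,916.600,806.022
fish,2.161,0.000,54.748,18.279,5.602,131.863,598.335,1069.889
meat,3.602,0.000,113.909,27.821,3.224,159.899,659.222,1777.112
eggs,0.000,0.000,96.833,7.723,0.729,114.970,734.555,1313.059
pulses,415.151,82.418,26.448,4.219,0.036,170.941,258.464,2814.574
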