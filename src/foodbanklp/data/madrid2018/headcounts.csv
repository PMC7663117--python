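sex,age_lo,age_hi,headcount
men,9,13,7664
women,9,13,8920
men,14,18,8292
women,14,18,9317
men,19,30,20905
women,19,30,22996
men,31,50,23217
women,31,50,24784
men,51,70,18543
women,51,70,16774
men,71,75,2362
women,71,75,2563
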