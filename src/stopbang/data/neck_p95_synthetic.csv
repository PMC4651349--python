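sex,age_years,p95_cm
male,9,31.4
male,10,32.1
male,11,32.9
male,12,33.6
male,13,34.5
male,14,35.5
male,15,36.5
male,16,37.3
male,17,38.0
male,18,38.5
female,9,29.8
female,10,30.5
female,11,31.2
female,12,31.9
female,13,32.7
female,14,33.4
female,15,34.0
female,16,34.5
female,17,34.9
female,18,35.2
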