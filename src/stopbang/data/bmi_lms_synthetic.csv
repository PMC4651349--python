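sex,age_months,L,M,S
male,108,-2.2,16.6,0.13
male,120,-2.2,17.189,0.13
male,132,-2.2,17.778,0.13
male,144,-2.2,18.367,0.13
male,156,-2.2,18.956,0.13
male,168,-2.2,19.544,0.13
male,180,-2.2,20.133,0.13
male,192,-2.2,20.722,0.13
male,204,-2.2,21.311,0.13
male,216,-2.2,21.9,0.13
female,108,-2.1,16.9,0.135
female,120,-2.1,17.389,0.135
female,132,-2.1,17.878,0.135
female,144,-2.1,18.367,0.135
female,156,-2.1,18.856,0.135
female,168,-2.1,19.344,0.135
female,180,-2.1,19.833,0.135
female,192,-2.1,20.322,0.135
female,204,-2.1,20.811,0.135
female,216,-2.1,21.3,0.135
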