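sex,age_months,L,M,S
male,108,1.0,133.5,0.045
male,120,1.0,138.5,0.045
male,132,1.0,143.5,0.045
male,144,1.0,149.5,0.045
male,156,1.0,156.5,0.045
male,168,1.0,163.5,0.045
male,180,1.0,169.0,0.045
male,192,1.0,172.5,0.045
male,204,1.0,174.5,0.045
male,216,1.0,175.5,0.045
female,108,1.0,133.0,0.042
female,120,1.0,138.5,0.042
female,132,1.0,144.5,0.042
female,144,1.0,151.0,0.042
female,156,1.0,156.5,0.042
female,168,1.0,160.0,0.042
female,180,1.0,162.0,0.042
female,192,1.0,163.0,0.042
female,204,1.0,163.5,0.042
female,216,1.0,163.8,0.042
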