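sex,measure,intercept,a1,a2,a3,a4,h1,h2,h3,h4,sd
male,systolic,102.19768,1.82416,0.12776,0.00249,-0.00135,2.73157,-0.19618,-0.04659,0.00947,10.7128
female,systolic,102.01027,1.94397,0.00598,-0.00789,-0.00059,2.03526,0.02534,-0.01884,0.00121,10.4855
male,diastolic,61.01217,0.68314,-0.09835,0.01711,0.00045,1.46993,-0.07849,-0.03144,0.00967,11.6032
female,diastolic,60.5051,1.01301,0.01157,0.00424,-0.00137,1.16641,0.12795,-0.03869,-0.00079,10.9573
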