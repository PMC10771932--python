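lobe,generation,mean,se
LUL,2,0.567,0.005
LUL,3,0.423,0.003
LUL,4,0.290,0.003
LUL,5,0.213,0.002
LUL,6,0.183,0.002
LUL,7,0.167,0.002
LLL,2,0.561,0.005
LLL,3,0.427,0.004
LLL,4,0.330,0.003
LLL,5,0.254,0.002
LLL,6,0.212,0.002
LLL,7,0.186,0.002
RUL,2,0.554,0.005
RUL,3,0.379,0.006
RUL,4,0.257,0.003
RUL,5,0.203,0.002
RUL,6,0.174,0.002
RUL,7,0.159,0.002
RML,3,0.406,0.005
RML,4,0.292,0.003
RML,5,0.221,0.002
RML,6,0.183,0.002
RML,7,0.164,0.002
RLL,3,0.566,0.007
RLL,4,0.424,0.006
RLL,5,0.299,0.003
RLL,6,0.245,0.002
RLL,7,0.218,0.002
RLL,8,0.196,0.002
RLL,9,0.175,0.002
RLL,10,0.167,0.002
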