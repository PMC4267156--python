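method,model,status_0,status_1,status_2,status_3_or_4
observed,0,0.8719,0.7273,0.5941,0.5941
ols,3,0.8518,0.7584,0.6499,0.5886
ols,4,0.8537,0.7581,0.6518,0.5883
ols,5,0.856,0.7571,0.6495,0.5842
tobit,3,0.889,0.7784,0.6498,0.5772
tobit,4,0.8913,0.778,0.652,0.5768
tobit,5,0.8944,0.7766,0.649,0.571
clad,3,0.8478,0.759,0.6558,0.6004
clad,4,0.8512,0.758,0.6545,0.5948
clad,5,0.8505,0.7541,0.6487,0.5829
quantile,3,0.8478,0.759,0.6558,0.6004
quantile,4,0.8512,0.758,0.6545,0.5948
quantile,5,0.8505,0.7541,0.6487,0.5829
lqr,3,0.8341,0.7548,0.6526,0.592
lqr,4,0.8349,0.7532,0.6507,0.5886
lqr,5,0.8387,0.7508,0.6422,0.5733
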