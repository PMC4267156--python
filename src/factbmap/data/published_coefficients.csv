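method,model,term,estimate
ols,1,const,0.2901
ols,1,PWB,0.012
ols,1,SWB,-0.0003
ols,1,EWB,0.0042
ols,1,FWB,0.0046
ols,1,BCS,0.0035
ols,2,const,0.3071
ols,2,PWB,0.0127
ols,2,SWB,-0.0003
ols,2,EWB,0.0062
ols,2,FWB,0.0048
ols,3,const,0.3064
ols,3,PWB,0.0125
ols,3,FWB,0.0052
ols,3,BCS,0.0048
ols,4,const,0.2846
ols,4,PWB,0.0121
ols,4,EWB,0.0041
ols,4,FWB,0.0044
ols,4,BCS,0.0034
ols,5,const,0.3031
ols,5,PWB,0.0128
ols,5,EWB,0.0061
ols,5,FWB,0.0046
tobit,1,const,0.1983
tobit,1,PWB,0.0144
tobit,1,SWB,0.0006
tobit,1,EWB,0.005
tobit,1,FWB,0.0048
tobit,1,BCS,0.0045
tobit,2,const,0.22
tobit,2,PWB,0.0153
tobit,2,SWB,0.0007
tobit,2,EWB,0.0077
tobit,2,FWB,0.0051
tobit,3,const,0.2342
tobit,3,PWB,0.0147
tobit,3,FWB,0.006
tobit,3,BCS,0.0063
tobit,4,const,0.2077
tobit,4,PWB,0.0142
tobit,4,EWB,0.0051
tobit,4,FWB,0.0051
tobit,4,BCS,0.0046
tobit,5,const,0.2318
tobit,5,PWB,0.0152
tobit,5,EWB,0.0078
tobit,5,FWB,0.0054
clad,1,const,0.3062
clad,1,PWB,0.0119
clad,1,SWB,-0.0004
clad,1,EWB,0.0041
clad,1,FWB,0.0037
clad,1,BCS,0.0036
clad,2,const,0.3208
clad,2,PWB,0.0121
clad,2,SWB,-0.0003
clad,2,EWB,0.0054
clad,2,FWB,0.0054
clad,3,const,0.32
clad,3,PWB,0.0123
clad,3,FWB,0.0039
clad,3,BCS,0.0054
clad,4,const,0.2948
clad,4,PWB,0.0122
clad,4,EWB,0.0042
clad,4,FWB,0.0037
clad,4,BCS,0.0035
clad,5,const,0.3149
clad,5,PWB,0.0121
clad,5,EWB,0.0054
clad,5,FWB,0.0053
quantile,1,const,0.3062
quantile,1,PWB,0.0119
quantile,1,SWB,-0.0004
quantile,1,EWB,0.0041
quantile,1,FWB,0.0037
quantile,1,BCS,0.0036
quantile,2,const,0.3208
quantile,2,PWB,0.0121
quantile,2,SWB,-0.0003
quantile,2,EWB,0.0054
quantile,2,FWB,0.0054
quantile,3,const,0.32
quantile,3,PWB,0.0123
quantile,3,FWB,0.0039
quantile,3,BCS,0.0054
quantile,4,const,0.2948
quantile,4,PWB,0.0122
quantile,4,EWB,0.0042
quantile,4,FWB,0.0037
quantile,4,BCS,0.0035
quantile,5,const,0.3149
quantile,5,PWB,0.0121
quantile,5,EWB,0.0054
quantile,5,FWB,0.0053
lqr,1,const,-1.6525
lqr,1,PWB,0.0684
lqr,1,SWB,0.0001
lqr,1,EWB,0.0155
lqr,1,FWB,0.023
lqr,1,BCS,0.0216
lqr,2,const,-1.6097
lqr,2,PWB,0.071
lqr,2,SWB,-0.0035
lqr,2,EWB,0.032
lqr,2,FWB,0.0312
lqr,3,const,-1.575
lqr,3,PWB,0.0678
lqr,3,FWB,0.0247
lqr,3,BCS,0.0301
lqr,4,const,-1.6489
lqr,4,PWB,0.0683
lqr,4,EWB,0.0157
lqr,4,FWB,0.023
lqr,4,BCS,0.0214
lqr,5,const,-1.6678
lqr,5,PWB,0.0722
lqr,5,EWB,0.0308
lqr,5,FWB,0.0295
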