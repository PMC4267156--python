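method,model,r2,adj_r2,mse,mad
ols,1,0.4975,0.4867,0.0132,0.0913
ols,2,0.487,0.4782,0.0135,0.0918
ols,3,0.489,0.4824,0.0135,0.0925
ols,4,0.4973,0.4887,0.0132,0.0913
ols,5,0.487,0.4804,0.0135,0.0919
tobit,1,0.4965,0.4856,0.0143,0.0934
tobit,2,0.4861,0.4773,0.0146,0.0937
tobit,3,0.4887,0.4821,0.0145,0.0945
tobit,4,0.4971,0.4885,0.0143,0.0934
tobit,5,0.4869,0.4803,0.0145,0.0936
clad,1,0.4968,0.486,0.0133,0.0912
clad,2,0.4863,0.4775,0.0135,0.0917
clad,3,0.4873,0.4807,0.0135,0.0923
clad,4,0.4968,0.4882,0.0133,0.0913
clad,5,0.4862,0.4796,0.0135,0.0917
quantile,1,0.4968,0.486,0.0133,0.0912
quantile,2,0.4863,0.4775,0.0135,0.0917
quantile,3,0.4873,0.4807,0.0135,0.0923
quantile,4,0.4968,0.4882,0.0133,0.0913
quantile,5,0.4862,0.4796,0.0135,0.0917
lqr,1,0.4686,0.4571,0.0141,0.0946
lqr,2,0.4596,0.4503,0.0143,0.0949
lqr,3,0.462,0.4551,0.0143,0.0953
lqr,4,0.4687,0.4596,0.0141,0.0946
lqr,5,0.4597,0.4528,0.0143,0.095
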