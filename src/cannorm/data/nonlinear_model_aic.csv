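response,model,k,AIC
size,asymptotic,3,244.7364
size,power,3,244.5961
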