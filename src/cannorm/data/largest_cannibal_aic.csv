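response,model_id,k,AIC
size,1,2,54.0536
size,2,2,51.5745
size,3,2,46.2726
size,4,2,52.7792
size,5,3,48.1799
size,6,4,48.8814
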