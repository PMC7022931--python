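variable_id,rat1,rat2
peak_101,1.8,-0.9
peak_205,0.4,0.6
peak_317,2.2,-1.1
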