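variable_id,rat1,rat2
peak_101,1.5,-1.2
peak_205,0.5,0.4
peak_317,1.9,-0.8
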