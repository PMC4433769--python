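name,scale_range,lower_is_better
LSAS,144,true
CGI-S,7,true
BSPS,72,true
FNE,30,true
FQ-SP,40,true
SADS,28,true
SPAI-SP,192,true
SDS,30,true
SPIN,68,true
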