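node_id,action
ST13,inhibit
IL-1R,inhibit
CAMK1,inhibit
SLC1A1,inhibit
AQP4,inhibit
TAB2,inhibit
GABRG2,enhance
APBA2,enhance
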