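node_id,action
EPHB2,inhibit
EGFR,inhibit
ARRB1,inhibit
TNFR,inhibit
FADD,inhibit
CDK5,enhance
AIG1,enhance
APC,enhance
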