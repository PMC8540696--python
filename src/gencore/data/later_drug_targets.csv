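drug,target,effect
trazodone,EPHB2,inhibit
trazodone,EGFR,inhibit
trazodone,ARRB1,inhibit
trazodone,TNFR,inhibit
trazodone,FADD,inhibit
trazodone,CDK5,enhance
trazodone,AIG1,enhance
trazodone,APC,enhance
tideglusib,EPHB2,inhibit
tideglusib,EGFR,inhibit
tideglusib,ARRB1,inhibit
tideglusib,TNFR,inhibit
tideglusib,FADD,inhibit
tideglusib,CDK5,enhance
tideglusib,APC,enhance
epothilone D,EPHB2,inhibit
epothilone D,EGFR,inhibit
epothilone D,ARRB1,inhibit
epothilone D,TNFR,inhibit
epothilone D,FADD,inhibit
epothilone D,CDK5,enhance
epothilone D,AIG1,enhance
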