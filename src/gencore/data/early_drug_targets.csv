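drug,target,effect
duloxetine,ST13,inhibit
duloxetine,IL-1R,inhibit
duloxetine,CAMK1,inhibit
duloxetine,SLC1A1,inhibit
duloxetine,AQP4,inhibit
duloxetine,TAB2,inhibit
duloxetine,GABRG2,enhance
duloxetine,APBA2,enhance
sulindac,ST13,inhibit
sulindac,IL-1R,inhibit
sulindac,CAMK1,inhibit
sulindac,SLC1A1,inhibit
sulindac,AQP4,inhibit
sulindac,GABRG2,enhance
sulindac,APBA2,enhance
avagacestat,ST13,inhibit
avagacestat,IL-1R,inhibit
avagacestat,CAMK1,inhibit
avagacestat,SLC1A1,inhibit
avagacestat,TAB2,inhibit
avagacestat,GABRG2,enhance
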