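fa,omega
18:1,omega-9
20:1,omega-9
22:1,omega-9
24:1,omega-9
18:2,omega-6
20:2,omega-6
20:3,omega-6
20:4,omega-6
22:4,omega-6
20:5,omega-3
22:6,omega-3
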