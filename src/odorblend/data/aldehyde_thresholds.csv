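name,cas,molecular_weight,threshold_mg_m3
PA,123-38-6,58.08,0.0406
BA,123-72-8,72.11,0.0207
IBA,78-84-2,72.11,0.0484
VA,110-62-3,86.13,0.0205
IVA,590-86-3,86.13,0.0217
HEX,66-25-1,100.16,0.0124
HEP,117-71-7,114.19,0.0260
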