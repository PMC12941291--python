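compound,rfd_ng_kg_bw_day
TPhP,70000
EHDPP,6000
TBOEP,15000
TnBP,10000
TPPO,20000
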