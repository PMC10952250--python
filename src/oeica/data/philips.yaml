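# Dual-echo dynamic lung SPGR protocol, 3 T Philips-style implementation.
# TE pair as published for this protocol. TR and flip angle are protocol-like
# defaults chosen so the simulated lung enhancement crosses zero at
# TE = 0.23 ms, consistent with the published sequence simulations.
tr_ms: 2.61
flip_deg: 2.0
te_ms: [0.72, 1.2]
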