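# Dual-echo dynamic lung SPGR protocol, 3 T Siemens-style implementation.
# Longer TE pair as published for this vendor's sequence; TR/flip as for the
# Philips-style file (vendor-specific values are not publicly tabulated).
tr_ms: 2.61
flip_deg: 2.0
te_ms: [0.81, 1.51]
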