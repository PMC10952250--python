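# Synthetic inert chest-wall tissue for the digital phantom: identical air and
# O2 relaxation times, hence zero oxygen enhancement. Not a literature value.
t1_air_ms: 1000.0
t1_oxy_ms: 1000.0
t2star_air_ms: 30.0
t2star_oxy_ms: 30.0
rho: 0.6
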