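# Oxygenated (arterial) blood relaxation times at 3 T under air and 100% O2.
# T2* lengthens under O2 (less deoxyhemoglobin); T1 shortens (dissolved O2).
t1_air_ms: 1649.0
t1_oxy_ms: 1354.0
t2star_air_ms: 59.4
t2star_oxy_ms: 72.5
rho: 1.0
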