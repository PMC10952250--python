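# Lung parenchyma relaxation times at 3 T under air and 100% O2 breathing
# (literature values for healthy lung). Proton density relative to blood.
t1_air_ms: 1281.0
t1_oxy_ms: 1102.0
t2star_air_ms: 0.68
t2star_oxy_ms: 0.62
rho: 0.25
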