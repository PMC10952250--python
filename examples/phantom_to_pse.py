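"""Full pipeline on the digital phantom: phantom -> ICA -> enhancement map.

Generates a dual-echo dynamic lung phantom with a known -8% lung enhancement
plus respiratory/cardiac confounds and noise, runs the temporal-ICA sweep
with automatic OE-component selection on echo 1, and compares the recovered
median lung enhancement (raw vs reconstructed) against the injected truth.
"""

import numpy as np

from oeica import process_echo
from oeica.phantom import generate_phantom
from oeica.validation import study_config

cfg = study_config(seed=1)  # -8% lung truth, sigma=0.05, a_resp=0.03
series, masks, truth = generate_phantom(cfg)
res = process_echo(series[0], masks, cfg.protocol, k_min=5, k_max=15, seed=1)

truth_med = float(np.median(truth.pse_maps[0][masks.lung]))
print(f"selected OE component: K={res.component.k}, index={res.component.index}, "
      f"rho={res.component.rho:.3f}, retries={res.component.retries}")
print(f"injected lung PSE (median): {truth_med:.2f} %")
print(f"raw  median lung PSE:       {res.summary_mri.median_lung_pse:.2f} % "
      f"(IQR {res.summary_mri.iqr_lung_pse:.2f})")
print(f"ICA  median lung PSE:       {res.summary_ica.median_lung_pse:.2f} % "
      f"(IQR {res.summary_ica.iqr_lung_pse:.2f})")
print("\nrho is the Spearman correlation of the selected component against the")
print("modelled gas-cycle waveform; the ICA map's tighter IQR reflects the")
print("confound and noise variance removed by keeping only the OE component.")
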