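# oeica — temporal-ICA analysis of dynamic oxygen-enhanced lung MRI

Dynamic oxygen-enhanced MRI (OE-MRI) of the lung measures the signal change
induced by breathing 100% O2 instead of air.  At 3 T the oxygen-induced
change is small and buried under respiratory and cardiac signal modulation
and noise, particularly in lung parenchyma whose T2\* is well under a
millisecond.  `oeica` implements an automatic analysis pipeline that
separates the oxygen-enhancement signal from these confounds with temporal
independent component analysis (ICA), driven by a cyclic gas challenge:

1. the delivered gas alternates between air and 100% O2 (90 s periods,
   three cycles, after a 90 s air baseline), imprinting a known temporal
   modulation on the oxygen response;
2. temporal ICA (FastICA) is applied to the thoracic-masked voxel × time
   matrix of each echo, repeatedly, sweeping the number of components K;
3. every component of every run is rank-correlated (Spearman ρ) against a
   sinusoidal model of the gas cycle; the component with the greatest |ρ|
   is selected automatically — re-running the sweep with fresh seeds if
   |ρ| < 0.4;
4. the selected component is reconstructed into image space and the
   percentage signal enhancement is mapped,

   PSE(v) = 100 · (SI_oxy(v) − SI_air(v)) / SI_air(v),

   with SI_air the mean of the first 60 dynamics (the air baseline) and
   SI_oxy the mean of the last five dynamics of each O2 period.

The package also ships:

- an SPGR steady-state signal model,
  S = ρ sin α (1 − E1)/(1 − cos α · E1) · e^(−TE/T2\*), E1 = e^(−TR/T1),
  that predicts the opposite enhancements of lung tissue (negative PSE
  above TE ≈ 0.23 ms, where T2\* shortening by gaseous O2 dominates) and
  oxygenated blood (small positive PSE at all TE);
- a digital dynamic-lung phantom with known ground-truth enhancement,
  respiratory/cardiac confounds and noise, so the whole pipeline is
  testable without any acquired data;
- test-retest agreement statistics: Bland–Altman bias and limits of
  agreement, the repeatability coefficient RC = 1.96·SD(d), and the
  two-way single-measure absolute-agreement intraclass correlation
  ICC(A,1), with the 0.5/0.75/0.9 moderate/good/excellent bands.

## Worked example

`examples/phantom_to_pse.py` generates a phantom with a known −8% lung
enhancement (noise σ = 0.05 of the lung baseline, 3% respiratory and 2%
cardiac modulation), runs the pipeline on echo 1, and prints:

```
selected OE component: K=11, index=0, rho=0.687, retries=0
injected lung PSE (median): -8.00 %
raw  median lung PSE:       -7.74 % (IQR 1.85)
ICA  median lung PSE:       -7.97 % (IQR 0.69)
```

The selected component correlates at ρ = 0.69 with the gas-cycle model
(well above the 0.4 quality threshold); the reconstructed map recovers the
injected enhancement to 0.03 percentage points while more than halving the
IQR — the variance removed is confound and noise power that contaminates
the raw map.  The other examples show the TE-dependence of the simulated
enhancement (`signal_simulation.py`), the suppression of the
respiratory-band spectral amplitude from 0.54 to 0.01 of the gas-frequency
peak (`spectral_cleanup.py`), and agreement statistics across repeat
pipeline applications (`repeatability_stats.py`).

A command-line interface wraps the same library:

```sh
oeica simulate --out phantom/ --seed 5
oeica run --echo1 phantom/echo1.nii.gz --echo2 phantom/echo2.nii.gz \
      --thoracic phantom/thoracic.nii.gz --lung phantom/lung.nii.gz \
      --protocol phantom/protocol.yaml --kmin 22 --kmax 72 --out results/
oeica simulate-signal --tissue lung --te-range 0:2:0.01
oeica agreement --scan1 s1.csv --scan2 s2.csv --metric median_pse
oeica repeat-ica --n-repeats 5
```

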