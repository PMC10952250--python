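# Methods

## The problem and the model

Breathing 100% O2 changes the lung MR signal through two competing
mechanisms.  Dissolved molecular O2 is paramagnetic and shortens T1 in
tissue water and blood plasma, raising the steady-state SPGR signal.
Gaseous O2 in the airspaces has a higher magnetic susceptibility than air,
steepening the gas–tissue susceptibility gradients and shortening lung
T2\*, which lowers the signal at any nonzero TE.  In oxygenated blood there
is no gas–tissue interface and (in healthy subjects) hemoglobin is already
near full saturation on air, so the T1 effect dominates and T2\* lengthens
slightly.  The enhancement metric is the percentage signal enhancement

    PSE(v) = 100 · (SI_oxy(v) − SI_air(v)) / SI_air(v),

and the sequence model is the ideal spoiled gradient echo,

    S = ρ sin α (1 − E1) / (1 − cos α E1) · exp(−TE/T2*),  E1 = exp(−TR/T1),

with perfect spoiling assumed (no spoiling details are modelled; slice
profile, B0/B1 inhomogeneity and noise floors are out of scope).  Setting
S_oxy(TE) = S_air(TE) gives the closed-form sign-crossover

    TE0 = ln(f_ratio) / (1/T2*_oxy − 1/T2*_air),

where f_ratio is the ratio of the T1-recovery factors.  With the bundled
lung relaxation times (T1 1281→1102 ms, T2\* 0.68→0.62 ms under O2) and
the dual-echo protocol parameters, TE0 = 0.23 ms: the lung enhancement is
slightly positive below that echo time and increasingly negative above it,
while blood enhancement (T1 1649→1354 ms, T2\* 59.4→72.5 ms) is positive
and slowly increasing at every TE.  The `find_crossover_te` root finder
uses bisection to |PSE| < 1e−10 and is checked against the closed form; a
missing sign change is reported as a distinct "no crossover" condition
(blood never crosses).

Sequence parameter files: the dual-echo TE pairs (0.72/1.2 ms and
0.81/1.51 ms for the two vendor implementations) are the published
protocol values.  TR and flip angle of such protocols are not publicly
tabulated; the bundled defaults (TR 2.61 ms, flip 2°) are protocol-like
values chosen once so that the simulated lung crossover lands at the
published 0.23 ms — any (TR, α) pair on that one-parameter family gives
identical PSE behaviour near the protocol TEs.

## Temporal ICA and automatic component selection

Within the thoracic mask each voxel time course is modelled as a linear
mixture of K independent temporal sources: X (V×T) ≈ mean_v + A·S with S
the unit-variance source time courses and A (V×K) their spatial maps.
This is the "temporal ICA" orientation — sources are time courses, mixing
weights are images — which makes reconstruction well defined.  Sources
are estimated by FastICA (fixed-point negentropy maximisation, logcosh
contrast, tol 1e−4, max 1000 iterations; non-convergent runs are flagged
but retained).  Whitening retains exactly K principal components per run.

Because the true number of sources is unknown and ICA ordering is
arbitrary, ICA is re-run for every K in a sweep (default 22–72, i.e. 51
instances, configurable; the bundled validation studies use 5–15 on the
small phantom).  Every component of every run is compared with a reference
waveform — flat at −1 during the air baseline, then
−cos(π(t−t_sw)/gas_period), so each air→O2 switch is a minimum and each
O2-period end a maximum — by Spearman rank correlation (average ranks for
ties).  Only the rank pattern of the reference matters, since Spearman
correlation is invariant to monotone rescaling.  The winner is the
component with the greatest |ρ| (ties: smaller K, then smaller component
index).  If the winner falls below the 0.4 quality threshold the entire
sweep is repeated with seed + 10000·retry, up to 5 retries, after which
the best component found is returned flagged `below_threshold`.  The
winner's time course is sign-oriented so ρ ≥ 0; reconstruction
(mean + map·course, no non-negativity clipping) is invariant to the joint
sign flip and to any scale gauge (c·course, map/c).

Echoes are processed independently end to end.  Per-run seeds are
seed + K, so a run manifest (seeds, K, component index, retries) suffices
to reproduce a result bit for bit.

## Enhancement mapping and spectra

SI_air averages the first 60 dynamics (= the 90 s baseline at the default
1.5 s dynamic interval); SI_oxy averages the last five dynamics of each O2
period (15 images over three cycles), i.e. the wash-in plateau.  The map
is algebraically the mean of the PSE time series over the SI_oxy window,
and both are invariant to global intensity rescaling.  Voxels whose
baseline falls below 1e−6 of the mean baseline are masked out (the ratio
is undefined at zero baseline) and reported.  Lung summaries are the
median and IQR (Q3−Q1, linear-interpolation quantiles — the convention is
fixed here because none is standard) over the lung-parenchyma mask,
optionally per slice; a slice with no valid lung voxels reports missing,
never zero.

Spectral QC uses the one-sided amplitude spectrum of the mean-removed
median-lung PSE time series, normalised to its maximum.  Because protocol
frequencies rarely land on FFT bins, band queries (default: gas band
3–8 mHz around f_OE = 1/(2·90 s); respiratory 0.2–0.33 Hz; aliased cardiac
0.08–0.18 Hz at the 1.5 s sampling) read the peak as a maximum over the
band.

## The digital phantom

The phantom emulates a motion-corrected (registered) free-breathing
dual-echo dynamic series on a coarse grid — four coronal slices of 32×32
by default, two elliptical lungs with ~4% of lung voxels replaced by
bright vessels, a heart ellipse, and an inert chest-wall background.  Per
voxel and dynamic,

    SI(v,t) = SI_base(v)·[1 + PSE_truth(v)/100 · w(t)]
              ·[1 + a_resp·g_resp(v)·sin(2π f_resp t)]
              ·[1 + a_card·g_card(v)·sin(2π f_card t)] + N(0, σ·SI_lung),

where SI_base comes from the SPGR model under air breathing per tissue
(lung ρ 0.25, blood 1.0, background 0.6 — lung parenchyma is dark), and
PSE_truth is SPGR-derived per tissue by default (−6.7%/−12.9% lung at the
two echoes, ≈+5.5% blood) or set explicitly per tissue (the validation
studies inject −8% lung / +5.5% blood).  w(t) is the O2 wash-in/out
waveform: zero during the air baseline, exponential approach to 1 during
O2 and decay during air with time constant τ = 15 s (a plausible alveolar
wash-in scale; ≪ the 90 s gas period so the plateau window is meaningful),
continuous across switches and clipped to [0,1].

The confound weights are spatially graded: g_resp ramps linearly toward
the lung base (respiratory density modulation is diaphragm-dominant) and
g_card is 1.5 in the heart vs 0.5 in lung vessels, each normalised so the
configured scalar is the mean amplitude.  This grading is not cosmetic:
with spatially uniform amplitudes the oxygen, respiratory and cardiac
sources would share only two spatial profiles (uniform-over-lung,
uniform-over-blood), a rank-deficient mixing that no linear unmixing —
ICA included — can separate even in principle.  Real anatomy does not
produce that degeneracy, and a phantom meant to test source separation
must not either.

Default study conditions: σ = 0.05 of the lung baseline signal (Gaussian;
Rician/magnitude bias is out of scope because the pipeline under test is
contrast-level), a_resp = 0.03 at 0.25 Hz, a_card = 0.02 at 0.13 Hz (an
aliased cardiac rate at the 1.5 s sampling; both distinct from
f_OE = 5.6 mHz).  The generator is bit-deterministic in its seed.  What
the phantom does *not* emulate: actual tissue motion and deformation
(inputs are assumed registered), coil/bias fields, k-space artefacts, and
anatomical realism beyond parametric ellipses — passing tests demonstrate
correct source separation and enhancement arithmetic under the stated
statistical structure, not robustness to registration failure or
motion-artefact structure in real scans.

## Agreement statistics

Bland–Altman: differences d = b − a; bias = mean(d); limits
bias ± 1.96·SD(d) with the sample SD (n−1); a bias is flagged significant
when 0 lies outside bias ± 1.96·SD(d)/√n.  The repeatability coefficient
is RC = 1.96·SD(d) (equivalently 1.96·√2·S_w), so RC equals half the LoA
width exactly.  ICC(A,1) follows the McGraw–Wong two-way single-measure
absolute-agreement form from ANOVA mean squares with subjects as rows and
sessions as columns; a zero-variance matrix yields an explicit "undefined"
(never silently 0 or 1).  Interpretation bands use half-open intervals
[0.5,0.75) moderate, [0.75,0.9) good, ≥0.9 excellent (the verbal
definitions are ambiguous at the endpoints; the boundary goes to the
higher band).  LoA use the 1.96 normal quantile rather than t-quantiles,
the standard Bland–Altman convention.

## Validation studies and problem sizes

`oeica.validation` runs the pipeline end to end on freshly generated
phantoms: a 10-seed recovery study (default phantom, −8% lung truth,
sweep K = 5–15) scoring component quality (ρ ≥ 0.4 at every seed,
median ≈ 0.69 — the ceiling is ≈ 0.75, the rank correlation between the
sinusoidal reference and the exponential wash-in truth), median-lung
recovery (relative error ≈ 1%, tolerance 15%), map error (reconstructed
RMSE ≈ 0.5% vs raw ≈ 1.25% against truth) and spectral confound
suppression (respiratory-band/gas-peak ratio ≈ 0.01 reconstructed vs
≈ 0.55 raw, threshold 0.2).  The algorithmic-uncertainty probe re-applies
ICA with fresh seeds to one fixed scan and compares its spread against the
scan-to-scan spread of fresh noise realisations; because FastICA's
run-to-run spread is itself scan-dependent, the repeat SD is summarised as
a median over two phantoms.  These sizes (32×32×4 grid, ~1400 thoracic
voxels, 420 dynamics) were chosen as the smallest grid at which recovery
quality plateaued — measured quality was indistinguishable at 48×48 and
64×64.

## Known limitations

- The ICA engine inherits FastICA's local-optima behaviour; the
  threshold-and-retry policy mitigates but does not eliminate it, which is
  precisely the "algorithmic uncertainty" the repeat-application probe
  quantifies.
- The reference waveform's exact phase is a convention; selection depends
  only on its rank pattern.
- No lung density correction is applied anywhere (by design — the ICA is
  expected to separate density-driven respiratory modulation instead).
- The agreement module assumes complete pairs; missing-data designs are
  out of scope.
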