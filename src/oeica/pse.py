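"""Percentage signal enhancement (PSE) maps, lung summaries, and spectra.

PSE quantifies the oxygen-induced signal change per voxel::

    PSE(v, t) = 100 * (SI(v, t) - SI_air(v)) / SI_air(v)          (time series)
    PSE(v)    = 100 * (SI_oxy(v) - SI_air(v)) / SI_air(v)         (map)

SI_air is the mean over the initial air baseline (first 60 dynamics by
default); SI_oxy averages the final five dynamics of each O2 period — the
plateau of the wash-in — so with three cycles the map pools 15 images.  The
map is, algebraically, the mean of the time series over the SI_oxy window.

Applied to the raw motion-corrected series these are PSE_MRI; applied to the
reconstructed OE-component series they are PSE_ICA.  The amplitude spectrum
of the median-lung PSE time series is the standard QC view: a clean OE
component shows a single peak at the gas-cycling frequency and little power
in the respiratory or aliased cardiac bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DynamicSeries, GasProtocol, PSEResult, ValidationError

__all__ = [
    "pse_timeseries",
    "pse_map",
    "summarize_lung",
    "spectrum",
    "band_amplitude",
    "SpectralBands",
    "PSEResult",
]

#: relative guard threshold on SI_air below which Eq-style ratios are unsafe
GUARD_EPS_REL = 1e-6


def _si_air(series: DynamicSeries, baseline_n: int) -> tuple[np.ndarray, np.ndarray]:
    if baseline_n >= series.n_dynamics:
        raise ValidationError(
            f"baseline of {baseline_n} dynamics must be shorter than the series ({series.n_dynamics})"
        )
    if baseline_n < 1:
        raise ValidationError("baseline must span at least one dynamic")
    si_air = series.data[:, :baseline_n].mean(axis=1)
    valid = si_air > GUARD_EPS_REL * si_air.mean()
    return si_air, valid


def pse_timeseries(
    series: DynamicSeries, baseline_n: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise PSE(t), percent; shape (slice, time, row, col).

    Returns ``(pse, valid)``: voxels whose baseline signal falls below the
    guard threshold are NaN in ``pse`` and False in ``valid``.
    """
    si_air, valid = _si_air(series, baseline_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        pse = 100.0 * (series.data - si_air[:, None]) / si_air[:, None]
    pse[~valid[:, None].repeat(series.n_dynamics, axis=1)] = np.nan
    return pse, valid


def pse_map(
    series: DynamicSeries,
    protocol: GasProtocol,
    baseline_n: int | None = None,
    n_plateau: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise PSE map, percent; shape (slice, row, col).

    SI_oxy averages the last ``n_plateau`` dynamics of each O2 period.
    Returns ``(map, valid)`` with the same guard convention as
    :func:`pse_timeseries`.
    """
    if baseline_n is None:
        baseline_n = protocol.baseline_n()
    oxy_idx = protocol.oxygen_window_indices(n_plateau)
    if oxy_idx.max() >= series.n_dynamics:
        raise ValidationError("O2 averaging window extends past the series")
    si_air, valid = _si_air(series, baseline_n)
    si_oxy = series.data[:, oxy_idx].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pse = 100.0 * (si_oxy - si_air) / si_air
    pse[~valid] = np.nan
    return pse, valid


def summarize_lung(
    pse: np.ndarray,
    lung_mask: np.ndarray,
    per_slice: bool = False,
    source: str = "MRI",
    echo_index: int = 0,
) -> PSEResult:
    """Median and IQR of a PSE map over the lung mask, optionally per slice.

    IQR = Q3 - Q1 with linear-interpolation quantiles.  A slice with no lung
    voxels (or only invalid ones) reports ``None``, never zero.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if pse.shape != lung_mask.shape:
        raise ValidationError("PSE map and lung mask shapes differ")
    vals = pse[lung_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("no valid lung voxels to summarise")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    per_slice_median: list[float | None] = []
    if per_slice:
        for s in range(pse.shape[0]):
            sv = pse[s][lung_mask[s]]
            sv = sv[np.isfinite(sv)]
            per_slice_median.append(float(np.median(sv)) if sv.size else None)
    return PSEResult(
        median_lung_pse=float(med),
        iqr_lung_pse=float(q3 - q1),
        per_slice_median=per_slice_median,
        source=source,
        echo_index=echo_index,
    )


@dataclass(frozen=True)
class SpectralBands:
    """Frequency bands (Hz) flagged on PSE spectra.

    Defaults suit 1.5 s sampling: the gas band brackets f_OE for a 90 s gas
    period, the respiratory band covers typical free-breathing rates, and the
    cardiac band covers where ~1 Hz heart rates alias to at this sampling.
    """

    gas: tuple[float, float] = (0.003, 0.008)
    respiratory: tuple[float, float] = (0.2, 0.33)
    cardiac: tuple[float, float] = (0.08, 0.18)


def spectrum(
    values: np.ndarray, dynamic_interval_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a mean-removed time series.

    Normalised so the maximum amplitude is 1 (all-zero if the series is
    constant).  Uniform sampling is assumed; pass the series' dynamic
    interval.  Requires at least 8 samples.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("spectrum expects a 1-D time series")
    if x.size < 8:
        raise ValidationError("need at least 8 samples for a spectrum")
    if dynamic_interval_s <= 0:
        raise ValidationError("dynamic interval must be positive")
    freqs = np.fft.rfftfreq(x.size, d=dynamic_interval_s)
    if np.ptp(x) == 0:  # constant series: nothing left after mean removal
        return freqs, np.zeros_like(freqs)
    x = x - x.mean()
    amp = np.abs(np.fft.rfft(x))
    peak = amp.max()
    if peak > 0:
        amp = amp / peak
    return freqs, amp


def band_amplitude(
    freqs: np.ndarray, amps: np.ndarray, band: tuple[float, float]
) -> float:
    """Maximum spectral amplitude within ``band`` (inclusive edges).

    The band should span at least one FFT bin; protocol frequencies rarely
    fall exactly on a bin, so a band query is the robust way to read a peak.
    """
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValidationError(f"band {band} Hz contains no FFT bins")
    return float(amps[sel].max())
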