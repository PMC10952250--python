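"""Synthetic dual-echo dynamic lung phantom with known oxygen enhancement.

The phantom emulates a motion-corrected free-breathing dynamic lung series:
elliptical lungs (with bright vessel voxels), a heart region between them,
and inert chest-wall background on a coarse grid of four coronal slices.
Each tissue's baseline signal and its ground-truth oxygen enhancement come
from the SPGR signal model, so lung voxels enhance negatively and
blood-filled voxels positively at the default echo times.  On top of the
gas-driven enhancement the generator adds the confounds the ICA pipeline is
designed to remove — multiplicative respiratory and (aliased) cardiac
sinusoids — plus Gaussian noise.

Per voxel v and dynamic time t::

    SI(v,t) = SI_base(v) * (1 + pse(v)/100 * w(t))
                         * (1 + a_resp * sin(2 pi f_resp t)) [lung voxels]
                         * (1 + a_card * sin(2 pi f_card t)) [heart+vessel]
              + N(0, sigma * SI_lung_base)

where w(t) is the O2 wash-in/out waveform: 0 during the air baseline, an
exponential approach to 1 (time constant tau_s) during O2 periods, and an
exponential decay during the interleaved air periods, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import DynamicSeries, GasProtocol, MaskSet, ValidationError
from .signal_model import RelaxationSet, SequenceParams, load_sequence, load_tissue, pse_vs_te, spgr_signal

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "LABELS"]

#: tissue label codes in PhantomTruth.labels
LABELS = {"background": 0, "lung": 1, "vessel": 2, "heart": 3}


def _default_tissues() -> dict[str, RelaxationSet]:
    return {
        "lung": load_tissue("lung"),
        "blood": load_tissue("blood"),
        "background": load_tissue("background"),
    }


@dataclass
class PhantomConfig:
    """Study conditions of the digital phantom.

    Defaults follow the cyclic gas protocol of the dual-echo lung study:
    90 s air baseline, then air/O2 switched every 90 s for three full cycles,
    one dynamic image per 1.5 s (so the baseline is exactly 60 dynamics).
    """

    shape: tuple[int, int, int] = (4, 32, 32)  # (slices, rows, cols)
    protocol: GasProtocol = field(default_factory=GasProtocol)
    sequence: SequenceParams = field(default_factory=lambda: load_sequence("philips"))
    tissues: dict[str, RelaxationSet] = field(default_factory=_default_tissues)
    tau_s: float = 15.0  # O2 wash-in/out time constant
    a_resp: float = 0.03  # fractional respiratory modulation of lung voxels
    f_resp_hz: float = 0.25
    a_card: float = 0.02  # fractional cardiac modulation of heart/vessel voxels
    f_card_hz: float = 0.13  # aliased cardiac frequency at 1.5 s sampling
    sigma: float = 0.05  # noise SD as a fraction of the lung baseline signal
    vessel_fraction: float = 0.04  # fraction of lung voxels replaced by vessels
    include_heart: bool = True
    slice_gradient: float = 0.0  # per-slice multiplier (1 + g*slice) on lung PSE
    pse_override: dict[str, float] | None = None  # percent per tissue, all echoes
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("a_resp", self.a_resp), ("a_card", self.a_card), ("sigma", self.sigma)):
            if v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tau_s < 0:
            raise ValidationError("tau_s must be >= 0")
        f_oe = self.protocol.f_oe_hz
        for name, f in (("f_resp_hz", self.f_resp_hz), ("f_card_hz", self.f_card_hz)):
            if abs(f - f_oe) < 1e-12:
                raise ValidationError(f"{name} must differ from the gas-cycling frequency")
        self.protocol.n_dynamics  # raises with field names if timing is inconsistent


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the synthetic series."""

    pse_maps: list[np.ndarray]  # per echo, percent, shape (slice, row, col)
    oe_timecourse: np.ndarray  # w(t), unitless in [0, 1], length T
    labels: np.ndarray  # tissue label map, shape (slice, row, col)


def _ellipse(rows: int, cols: int, cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:rows, 0:cols]
    return ((rr - cr) / ar) ** 2 + ((cc_ - cc) / ac) ** 2 <= 1.0


def _label_map(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    ns, nr, nc = config.shape
    labels = np.zeros(config.shape, dtype=np.int8)
    # two lungs per slice, heart between and below; same layout on all slices
    left = _ellipse(nr, nc, nr * 0.5, nc * 0.30, nr * 0.30, nc * 0.16)
    right = _ellipse(nr, nc, nr * 0.5, nc * 0.70, nr * 0.30, nc * 0.16)
    lung2d = left | right
    heart2d = np.zeros_like(lung2d)
    if config.include_heart:
        heart2d = _ellipse(nr, nc, nr * 0.62, nc * 0.50, nr * 0.16, nc * 0.14)
    for s in range(ns):
        labels[s][lung2d] = LABELS["lung"]
        labels[s][heart2d] = LABELS["heart"]
        lung_idx = np.flatnonzero((labels[s] == LABELS["lung"]).ravel())
        n_ves = int(round(config.vessel_fraction * lung_idx.size))
        if n_ves > 0:
            pick = rng.choice(lung_idx, size=n_ves, replace=False)
            labels[s].ravel()[pick] = LABELS["vessel"]
    return labels


def oe_waveform(protocol: GasProtocol, tau_s: float, times_s: np.ndarray) -> np.ndarray:
    """O2 wash-in/out waveform w(t) on the given time grid, in [0, 1].

    Zero during the air baseline; within each gas period the waveform relaxes
    exponentially toward 1 (O2) or 0 (air) from its value at the switch, so it
    is continuous across switches.  ``tau_s = 0`` gives the ideal square wave.
    """
    w = np.zeros_like(times_s, dtype=float)
    sw = protocol.switch_times_s
    w_at_switch = 0.0
    for k, t_on in enumerate(sw):
        is_o2 = k % 2 == 0
        t_end = t_on + protocol.gas_period_s
        seg = (times_s >= t_on) & (times_s < t_end)
        target = 1.0 if is_o2 else 0.0
        if tau_s == 0.0:
            w[seg] = target
            w_at_switch = target
        else:
            w[seg] = target + (w_at_switch - target) * np.exp(-(times_s[seg] - t_on) / tau_s)
            w_at_switch = target + (w_at_switch - target) * np.exp(-protocol.gas_period_s / tau_s)
    return np.clip(w, 0.0, 1.0)


def _tissue_for_label(label: int) -> str:
    return {0: "background", 1: "lung", 2: "blood", 3: "blood"}[label]


def generate_phantom(
    config: PhantomConfig,
) -> tuple[list[DynamicSeries], MaskSet, PhantomTruth]:
    """Generate one dynamic series per echo, the two masks, and the truth.

    Deterministic for a fixed config (seed included): repeated calls return
    bit-identical arrays.
    """
    protocol = config.protocol
    T = protocol.n_dynamics
    times = np.arange(T) * protocol.dynamic_interval_s
    rng = np.random.default_rng(config.seed)
    labels = _label_map(config, rng)
    w = oe_waveform(protocol, config.tau_s, times)

    lung_like = labels == LABELS["lung"]
    cardiac_like = (labels == LABELS["heart"]) | (labels == LABELS["vessel"])
    # Spatially weighted confound amplitudes (mean = the configured scalar).
    # Respiratory modulation grows linearly toward the lung base (diaphragm-
    # dominant motion); cardiac pulsatility is stronger in the heart than in
    # lung vessels.  Scalar amplitudes would make the confound maps exactly
    # proportional to the enhancement map inside each tissue, an unresolvable
    # (rank-deficient) mixing that real anatomy does not produce.
    nr = config.shape[1]
    resp_weight = np.zeros(config.shape)
    resp_weight[lung_like] = (2.0 * np.argwhere(lung_like)[:, 1] / max(nr - 1, 1))
    card_weight = np.where(labels == LABELS["heart"], 1.5, 0.0) + np.where(
        labels == LABELS["vessel"], 0.5, 0.0
    )
    resp_t = np.sin(2 * np.pi * config.f_resp_hz * times)
    card_t = np.sin(2 * np.pi * config.f_card_hz * times)

    slice_scale = 1.0 + config.slice_gradient * np.arange(config.shape[0])

    series: list[DynamicSeries] = []
    pse_maps: list[np.ndarray] = []
    for echo, te in enumerate(config.sequence.te_ms):
        base = np.zeros(config.shape)
        pse = np.zeros(config.shape)
        for code in LABELS.values():
            tissue = _tissue_for_label(code)
            relax = config.tissues[tissue]
            sel = labels == code
            if not sel.any():
                continue
            base[sel] = spgr_signal(relax.t1_air_ms, relax.t2star_air_ms, relax.rho, config.sequence, te)
            if config.pse_override is not None and tissue in config.pse_override:
                pse[sel] = config.pse_override[tissue]
            elif tissue != "background":
                pse[sel] = pse_vs_te(relax, config.sequence, te)
        if config.slice_gradient != 0.0:
            pse = pse * np.where(lung_like, slice_scale[:, None, None], 1.0)

        # (slice, time, row, col)
        si = base[:, None, :, :] * (1.0 + pse[:, None, :, :] / 100.0 * w[None, :, None, None])
        si = si * (
            1.0 + config.a_resp * resp_weight[:, None, :, :] * resp_t[None, :, None, None]
        )
        si = si * (
            1.0 + config.a_card * card_weight[:, None, :, :] * card_t[None, :, None, None]
        )
        lung_relax = config.tissues["lung"]
        si_lung_base = spgr_signal(
            lung_relax.t1_air_ms, lung_relax.t2star_air_ms, lung_relax.rho, config.sequence, te
        )
        if config.sigma > 0:
            si = si + rng.normal(0.0, config.sigma * si_lung_base, size=si.shape)
        si = np.clip(si, 0.0, None)
        series.append(
            DynamicSeries(si, protocol.dynamic_interval_s, echo_index=echo, te_ms=te)
        )
        pse_maps.append(pse)

    masks = MaskSet(lung=lung_like, thoracic=lung_like | cardiac_like)
    truth = PhantomTruth(pse_maps=pse_maps, oe_timecourse=w, labels=labels)
    return series, masks, truth


def noise_free(config: PhantomConfig) -> PhantomConfig:
    """Copy of ``config`` with noise and physiological confounds switched off."""
    return replace(config, sigma=0.0, a_resp=0.0, a_card=0.0)
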