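"""Spoiled gradient-echo (SPGR) steady-state signal model for oxygen contrast.

Inhaled 100% O2 acts on two relaxation parameters at once: dissolved molecular
O2 shortens T1 (raising the steady-state signal), while the higher magnetic
susceptibility of gaseous O2 in the airspaces shortens lung T2* (lowering the
signal at any nonzero TE).  In oxygenated blood there is no gas-tissue
interface; T1 shortening and a slight T2* lengthening (less deoxyhemoglobin)
both push the signal up.  The percentage signal enhancement (PSE) therefore
has opposite signs in lung parenchyma and in blood at the echo times of a
dual-echo lung protocol, and for lung it crosses zero at a short TE where the
T1 and T2* effects balance.

The model is the ideal RF-spoiled gradient-echo steady state::

    S(TE) = rho * sin(a) * (1 - E1) / (1 - cos(a) * E1) * exp(-TE / T2*),
    E1    = exp(-TR / T1)

with perfect spoiling assumed.  PSE(TE) = 100 * (S_oxy - S_air) / S_air.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .datatypes import ValidationError

__all__ = [
    "SequenceParams",
    "RelaxationSet",
    "NoCrossoverError",
    "spgr_signal",
    "pse_vs_te",
    "crossover_te_closed_form",
    "find_crossover_te",
    "load_sequence",
    "load_tissue",
]


class NoCrossoverError(ValueError):
    """PSE(TE) does not change sign on the searched interval."""


@dataclass(frozen=True)
class SequenceParams:
    """SPGR sequence settings. Times in milliseconds, flip angle in degrees."""

    tr_ms: float
    flip_deg: float
    te_ms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValidationError("TR must be positive")
        if not 0 < self.flip_deg < 180:
            raise ValidationError("flip angle must lie in (0, 180) degrees")
        for te in self.te_ms:
            if te < 0 or te >= self.tr_ms:
                raise ValidationError(f"TE {te} ms must satisfy 0 <= TE < TR")


@dataclass(frozen=True)
class RelaxationSet:
    """Tissue relaxation times (ms) under air and 100% O2 breathing.

    ``rho`` is the relative proton density; it cancels out of any PSE.
    """

    t1_air_ms: float
    t1_oxy_ms: float
    t2star_air_ms: float
    t2star_oxy_ms: float
    rho: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.t1_air_ms, self.t1_oxy_ms, self.t2star_air_ms, self.t2star_oxy_ms):
            if v <= 0:
                raise ValidationError("relaxation times must be positive")
        if self.rho <= 0:
            raise ValidationError("proton density must be positive")


def spgr_signal(
    t1_ms: float,
    t2star_ms: float,
    rho: float,
    seq: SequenceParams,
    te_ms: float | np.ndarray,
) -> float | np.ndarray:
    """Ideal spoiled-GRE steady-state signal at echo time ``te_ms``.

    Strictly positive; strictly increasing in T2* for TE > 0.
    """
    te = np.asarray(te_ms, dtype=float)
    if np.any(te < 0) or np.any(te >= seq.tr_ms):
        raise ValidationError("TE must satisfy 0 <= TE < TR")
    a = np.deg2rad(seq.flip_deg)
    e1 = np.exp(-seq.tr_ms / t1_ms)
    s = rho * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1) * np.exp(-te / t2star_ms)
    return s if s.ndim else float(s)


def pse_vs_te(
    relax: RelaxationSet, seq: SequenceParams, te_ms: float | np.ndarray
) -> float | np.ndarray:
    """Percentage signal enhancement 100*(S_oxy - S_air)/S_air at ``te_ms``.

    Independent of ``rho`` and of any overall signal scaling.
    """
    s_air = spgr_signal(relax.t1_air_ms, relax.t2star_air_ms, relax.rho, seq, te_ms)
    s_oxy = spgr_signal(relax.t1_oxy_ms, relax.t2star_oxy_ms, relax.rho, seq, te_ms)
    return 100.0 * (s_oxy - s_air) / s_air


def _t1_recovery_ratio(relax: RelaxationSet, seq: SequenceParams) -> float:
    a = np.deg2rad(seq.flip_deg)

    def f(t1: float) -> float:
        e1 = np.exp(-seq.tr_ms / t1)
        return (1.0 - e1) / (1.0 - np.cos(a) * e1)

    return f(relax.t1_oxy_ms) / f(relax.t1_air_ms)


def crossover_te_closed_form(relax: RelaxationSet, seq: SequenceParams) -> float:
    """TE at which PSE changes sign, in closed form.

    Setting S_oxy(TE) = S_air(TE) and solving for TE gives
    ``TE0 = ln(f_ratio) / (1/T2*_oxy - 1/T2*_air)`` where ``f_ratio`` is the
    ratio of the T1-recovery factors (oxy over air).  Equal T2* values with
    unequal T1 give no finite crossover.
    """
    dr2 = 1.0 / relax.t2star_oxy_ms - 1.0 / relax.t2star_air_ms
    log_ratio = np.log(_t1_recovery_ratio(relax, seq))
    if dr2 == 0.0:
        if log_ratio == 0.0:
            return 0.0
        raise NoCrossoverError("equal T2* values: PSE never changes sign")
    return float(log_ratio / dr2)


def find_crossover_te(
    relax: RelaxationSet,
    seq: SequenceParams,
    te_max_ms: float | None = None,
    tol_pse: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Locate the TE at which PSE(TE) = 0 by bisection on [0, te_max].

    ``te_max_ms`` defaults to 0.99*TR.  Raises :class:`NoCrossoverError` if
    PSE does not change sign on the interval — distinct from numerical
    failure, which raises ``RuntimeError``.
    """
    hi = 0.99 * seq.tr_ms if te_max_ms is None else te_max_ms
    lo = 0.0
    p_lo = float(pse_vs_te(relax, seq, lo))
    p_hi = float(pse_vs_te(relax, seq, hi))
    if abs(p_lo) < tol_pse:
        return lo
    if abs(p_hi) < tol_pse:
        return hi
    if np.sign(p_lo) == np.sign(p_hi):
        raise NoCrossoverError(
            f"no crossover: PSE({lo}) = {p_lo:.4g} and PSE({hi}) = {p_hi:.4g} share a sign"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = float(pse_vs_te(relax, seq, mid))
        if abs(p_mid) < tol_pse:
            return mid
        if np.sign(p_mid) == np.sign(p_lo):
            lo, p_lo = mid, p_mid
        else:
            hi = mid
    raise RuntimeError("bisection failed to reach the PSE tolerance")


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("oeica.data").joinpath(f"{name}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_sequence(name: str) -> SequenceParams:
    """Load a bundled scanner sequence parameter set ('philips' or 'siemens')."""
    d = _load_yaml(name)
    return SequenceParams(
        tr_ms=float(d["tr_ms"]),
        flip_deg=float(d["flip_deg"]),
        te_ms=tuple(float(t) for t in d["te_ms"]),
    )


def load_tissue(name: str) -> RelaxationSet:
    """Load a bundled tissue relaxation set ('lung', 'blood' or 'background')."""
    d = _load_yaml(name)
    return RelaxationSet(
        t1_air_ms=float(d["t1_air_ms"]),
        t1_oxy_ms=float(d["t1_oxy_ms"]),
        t2star_air_ms=float(d["t2star_air_ms"]),
        t2star_oxy_ms=float(d["t2star_oxy_ms"]),
        rho=float(d.get("rho", 1.0)),
    )
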