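"""Core containers shared across the pipeline.

Conventions
-----------
Dynamic image data are stored as 4-D float arrays ordered
``(slice, time, row, col)``.  Masks are boolean 3-D arrays ordered
``(slice, row, col)``.  All times are seconds unless a name says otherwise
(sequence timings in :mod:`oeica.signal_model` are milliseconds, as is
customary for TR/TE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """An input violated a contract of the pipeline."""


@dataclass
class DynamicSeries:
    """One echo's motion-corrected 4-D dynamic series.

    Parameters
    ----------
    data:
        Signal intensities, shape ``(n_slices, n_dynamics, n_rows, n_cols)``,
        arbitrary units, non-negative, no NaNs.
    dynamic_interval_s:
        Time between consecutive dynamic images (uniform sampling assumed).
    echo_index:
        0-based echo number; processing never mixes echoes.
    te_ms:
        Echo time of this echo, for bookkeeping only.
    voxel_size_mm:
        (row, col, slice) voxel dimensions, used when writing NIfTI.
    allow_negative:
        Reconstructed OE-component series may legitimately dip below zero
        (no clipping is applied at reconstruction); acquired data may not.
    """

    data: np.ndarray
    dynamic_interval_s: float
    echo_index: int = 0
    te_ms: float | None = None
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 10.0)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValidationError(
                f"dynamic series must be 4-D (slice, time, row, col); got {self.data.ndim}-D"
            )
        if self.data.shape[1] < 2:
            raise ValidationError("dynamic series needs at least 2 time points")
        if np.isnan(self.data).any():
            raise ValidationError("dynamic series contains NaNs")
        if not self.allow_negative and (self.data < 0).any():
            raise ValidationError("dynamic series contains negative intensities")
        if self.dynamic_interval_s <= 0:
            raise ValidationError("dynamic_interval_s must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        s, _, r, c = self.data.shape
        return (s, r, c)

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each dynamic, starting at 0."""
        return np.arange(self.n_dynamics) * self.dynamic_interval_s


@dataclass
class MaskSet:
    """Lung-parenchyma and full-thoracic-cavity masks.

    ``lung`` excludes major vasculature and is used for summary statistics;
    ``thoracic`` includes heart and major vessels and is the ICA domain.
    """

    lung: np.ndarray
    thoracic: np.ndarray

    def __post_init__(self) -> None:
        self.lung = np.asarray(self.lung, dtype=bool)
        self.thoracic = np.asarray(self.thoracic, dtype=bool)
        if self.lung.shape != self.thoracic.shape:
            raise ValidationError("lung and thoracic masks must share a shape")
        if not self.lung.any():
            raise ValidationError("lung mask is empty")
        if not self.thoracic.any():
            raise ValidationError("thoracic mask is empty")
        if (self.lung & ~self.thoracic).any():
            raise ValidationError("lung mask must be contained in the thoracic mask")


@dataclass
class GasProtocol:
    """Cyclic air / 100% O2 delivery schedule.

    The scan opens with ``baseline_s`` of air breathing, then alternates
    O2 and air periods of ``gas_period_s`` each, ``n_cycles`` times.  The
    gas-cycling frequency is ``f_oe = 1 / (2 * gas_period_s)``.
    """

    baseline_s: float = 90.0
    gas_period_s: float = 90.0
    n_cycles: int = 3
    dynamic_interval_s: float = 1.5

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.gas_period_s, self.dynamic_interval_s) <= 0:
            raise ValidationError("protocol timings must be positive")
        if self.n_cycles < 1:
            raise ValidationError("need at least one gas cycle")

    @property
    def duration_s(self) -> float:
        return self.baseline_s + 2 * self.n_cycles * self.gas_period_s

    @property
    def f_oe_hz(self) -> float:
        """Gas-cycling frequency: one full air+O2 cycle per 2*gas_period_s."""
        return 1.0 / (2.0 * self.gas_period_s)

    @property
    def n_dynamics(self) -> int:
        """Total dynamics implied by the schedule; must be integral."""
        t = self.duration_s / self.dynamic_interval_s
        if abs(t - round(t)) > 1e-9:
            raise ValidationError(
                "protocol duration is not a whole number of dynamics: "
                f"(baseline_s={self.baseline_s} + 2*{self.n_cycles}*"
                f"gas_period_s={self.gas_period_s}) / "
                f"dynamic_interval_s={self.dynamic_interval_s} = {t}"
            )
        return int(round(t))

    @property
    def switch_times_s(self) -> np.ndarray:
        """Gas-switch times, strictly increasing, starting with air->O2."""
        return self.baseline_s + self.gas_period_s * np.arange(2 * self.n_cycles)

    def oxygen_periods_s(self) -> list[tuple[float, float]]:
        """(start, end) of each 100% O2 inhalation period."""
        sw = self.switch_times_s
        return [(sw[2 * k], sw[2 * k] + self.gas_period_s) for k in range(self.n_cycles)]

    def oxygen_window_indices(self, n_last: int = 5) -> np.ndarray:
        """Dynamic indices of the last ``n_last`` images of each O2 period.

        These form the SI_oxy averaging window of the enhancement map.
        """
        dt = self.dynamic_interval_s
        per = int(round(self.gas_period_s / dt))
        if per < n_last:
            raise ValidationError(
                f"O2 period covers {per} dynamics, fewer than the {n_last} "
                "requested for the SI_oxy window"
            )
        idx: list[int] = []
        for start_s, end_s in self.oxygen_periods_s():
            end = int(round(end_s / dt))  # exclusive
            idx.extend(range(end - n_last, end))
        out = np.asarray(idx, dtype=int)
        if out.max() >= self.n_dynamics:
            raise ValidationError("O2 window extends past the end of the series")
        return out

    def baseline_n(self) -> int:
        """Number of dynamics in the initial air baseline."""
        return int(round(self.baseline_s / self.dynamic_interval_s))


@dataclass
class PSEResult:
    """Summary of a percentage-signal-enhancement map within the lung mask."""

    median_lung_pse: float
    iqr_lung_pse: float
    per_slice_median: list[float | None] = field(default_factory=list)
    source: str = "MRI"  # "MRI" (raw) or "ICA" (reconstructed)
    echo_index: int = 0
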