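"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPOCH_LEN_S = 15.0
#: lowest admissible sampling rate: twice the top gamma edge (58 Hz)
MIN_SAMPLING_RATE = 116.0


@dataclass
class RoiTimeSeries:
    """Per-subject parcel (ROI) time series.

    ``data`` is an ROI-by-sample real matrix.  ``epoch_flags`` marks each
    consecutive 15 s epoch as clean (True) or contaminated (False); the
    analysis keeps the first six clean epochs.
    """

    subject_id: str
    sampling_rate: float
    roi_ids: list[str]
    data: np.ndarray
    epoch_flags: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.epoch_flags = np.asarray(self.epoch_flags, dtype=bool)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.roi_ids):
            raise ValueError(
                f"data must be (n_rois, n_samples) with n_rois == len(roi_ids); "
                f"got {self.data.shape} for {len(self.roi_ids)} ROIs"
            )
        if self.sampling_rate <= MIN_SAMPLING_RATE:
            raise ValueError(
                f"sampling_rate must exceed {MIN_SAMPLING_RATE} Hz "
                f"(twice the 58 Hz top band edge); got {self.sampling_rate}"
            )
        n_epochs = int(self.duration // EPOCH_LEN_S)
        if len(self.epoch_flags) != n_epochs:
            raise ValueError(
                f"epoch_flags has length {len(self.epoch_flags)}; expected "
                f"{n_epochs} for a {self.duration:.1f} s recording"
            )

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


@dataclass
class ConnectivityRecord:
    """Symmetric imaginary-coherence matrix for one subject and band.

    At ROI level the diagonal is undefined (NaN).  At module level the
    diagonal holds the averaged within-module imaginary coherence (NaN
    only for singleton modules, which have no within-module ROI pair).
    """

    subject_id: str
    band: str
    level: str  # "roi" | "module"
    ids: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.level not in ("roi", "module"):
            raise ValueError(f"level must be 'roi' or 'module', got {self.level!r}")
        if self.values.shape != (n, n):
            raise ValueError(
                f"values must be {n}x{n} to match ids, got {self.values.shape}"
            )
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("imaginary coherence values must lie in [0, 1]")
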