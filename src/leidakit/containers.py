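"""Core in-memory containers shared across the pipeline.

The pipeline's atomic input is an ROI-by-time BOLD-like matrix with a
repetition time (TR) and subject/session/modality labels; rigid-body motion
traces ride along for quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RoiTimeseries:
    """One run of region-averaged BOLD-like signal.

    Parameters
    ----------
    data
        ``(n_roi, n_volumes)`` real matrix, one row per region.
    tr
        Repetition time in seconds (sampling interval of the columns).
    subject, session, modality
        Provenance labels; free-form strings.
    """

    data: np.ndarray
    tr: float
    subject: str = ""
    session: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_roi, n_volumes)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timeseries contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters for one run.

    ``params`` is ``(n_volumes, 6)``: translations in mm (x, y, z) followed by
    rotations in radians (about x, y, z).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must have shape (n_volumes, 6)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]
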