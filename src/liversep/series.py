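"""Container for complex multi-echo image data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams


@dataclass
class EchoSeries:
    """Complex mGRE stack, indexed (x, y, z, echo), plus acquisition metadata."""

    data: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"echo data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] != self.acq.n_echoes:
            raise ValueError(
                f"echo count {self.data.shape[-1]} does not match "
                f"acquisition metadata ({self.acq.n_echoes})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("echo data contains non-finite values")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)
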