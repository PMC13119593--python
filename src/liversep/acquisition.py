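"""Acquisition metadata for multi-echo gradient-echo (mGRE) series.

All times are in seconds, field strength in tesla, voxel sizes in mm.
The default protocol is a 3 T, 8-echo acquisition with TE1 = 2.6 ms and
echo spacing 2.7 ms, as used for ex vivo liver specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Proton gyromagnetic ratio over 2*pi, Hz/T.
GYROMAGNETIC_RATIO_HZ_PER_T = 42.58e6


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and geometry of an mGRE acquisition.

    Parameters
    ----------
    echo_times : tuple of float
        Echo times in seconds, strictly increasing and positive.
    field_strength : float
        Main field B0 in tesla.
    b0_direction : tuple of float
        Unit vector of the main field in the volume frame.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    fat_shift_hz : float
        Single-peak fat resonance offset relative to water, in Hz
        (about -440 Hz at 3 T, i.e. -3.45 ppm).
    flip_angle_deg : float
        Excitation flip angle in degrees (metadata only; the signal
        model works with relative proton densities).
    """

    echo_times: tuple = (0.0026, 0.0053, 0.0080, 0.0107, 0.0134,
                         0.0161, 0.0188, 0.0215)
    field_strength: float = 3.0
    b0_direction: tuple = (0.0, 0.0, 1.0)
    voxel_size: tuple = (0.88, 0.88, 1.0)
    fat_shift_hz: float = -440.0
    flip_angle_deg: float = 15.0

    def __post_init__(self):
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 3:
            raise ValueError(f"need at least 3 echoes, got {te.size}")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        b0 = np.asarray(self.b0_direction, dtype=float)
        if not np.isclose(np.linalg.norm(b0), 1.0, atol=1e-6):
            raise ValueError("b0_direction must have unit norm")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def echo_times_array(self) -> np.ndarray:
        return np.asarray(self.echo_times, dtype=float)

    @property
    def delta_te(self) -> float:
        """Mean echo spacing in seconds."""
        return float(np.mean(np.diff(self.echo_times_array)))

    @property
    def larmor_hz(self) -> float:
        """Larmor frequency gamma-bar * B0 in Hz (127.74 MHz at 3 T)."""
        return GYROMAGNETIC_RATIO_HZ_PER_T * self.field_strength

    def echoes_equally_spaced(self, rtol: float = 0.01) -> bool:
        d = np.diff(self.echo_times_array)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * d.mean()))

    def to_dict(self) -> dict:
        return {
            "echo_times": list(map(float, self.echo_times)),
            "field_strength": float(self.field_strength),
            "b0_direction": list(map(float, self.b0_direction)),
            "voxel_size": list(map(float, self.voxel_size)),
            "fat_shift_hz": float(self.fat_shift_hz),
            "flip_angle_deg": float(self.flip_angle_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        required = ["echo_times"]
        missing = [k for k in required if k not in d]
        if missing:
            raise KeyError(f"sidecar missing required field(s): {missing}")
        kwargs = {}
        for key_in, key_out in [
            ("echo_times", "echo_times"),
            ("field_strength", "field_strength"),
            ("b0_direction", "b0_direction"),
            ("voxel_size", "voxel_size"),
            ("fat_shift_hz", "fat_shift_hz"),
            ("flip_angle_deg", "flip_angle_deg"),
        ]:
            if key_in in d:
                v = d[key_in]
                kwargs[key_out] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)
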