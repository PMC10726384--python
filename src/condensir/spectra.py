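"""Container for 2D IR spectral cubes.

Sign convention: the ground-state bleach is *negative*, the excited-state
absorption (anharmonically red-shifted along the probe axis) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Spectrum2D:
    """A pump x probe x waiting-time signal cube.

    Parameters
    ----------
    pump, probe : strictly increasing frequency axes in cm^-1.
    waiting_times : waiting times Tw in ps, non-negative.
    cube : signal array of shape (n_tw, n_pump, n_probe), signed
        arbitrary units with the bleach negative.
    """

    pump: np.ndarray
    probe: np.ndarray
    waiting_times: np.ndarray
    cube: np.ndarray

    def __post_init__(self) -> None:
        self.pump = np.asarray(self.pump, dtype=float)
        self.probe = np.asarray(self.probe, dtype=float)
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)
        self.cube = np.asarray(self.cube, dtype=float)
        for ax, name in ((self.pump, "pump"), (self.probe, "probe")):
            if ax.ndim != 1 or len(ax) < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be 1-D strictly increasing")
        if np.any(self.waiting_times < 0):
            raise ValueError("waiting times must be non-negative")
        expected = (len(self.waiting_times), len(self.pump), len(self.probe))
        if self.cube.shape != expected:
            raise ValueError(
                f"cube shape {self.cube.shape} inconsistent with axes {expected}")

    def tw_index(self, tw: float, atol: float = 1e-9) -> int:
        """Index of waiting time ``tw``; raises if absent."""
        hits = np.flatnonzero(np.isclose(self.waiting_times, tw, atol=atol))
        if len(hits) == 0:
            raise ValueError(f"waiting time {tw} ps not present in cube")
        return int(hits[0])

    def at(self, tw: float) -> np.ndarray:
        """The (n_pump, n_probe) slice at waiting time ``tw``."""
        return self.cube[self.tw_index(tw)]
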