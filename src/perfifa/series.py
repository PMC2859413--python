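"""Container for a single-slice dynamic perfusion series.

A dynamic susceptibility-contrast (DSC) acquisition of one slice is a stack
of T images of the same P-pixel grid.  Throughout the package it is handled
as a T x P matrix whose rows are time frames and whose columns are pixel
time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DynamicSeries:
    """A T x P dynamic image series with acquisition metadata.

    Parameters
    ----------
    data:
        Real T x P matrix of image intensities (arbitrary units).  Row ``t``
        is the image acquired at ``frame_times[t]``, flattened in C order.
    grid_shape:
        (rows, cols) of the underlying image grid; ``rows * cols == P``.
    frame_times:
        Acquisition time of each frame in seconds, strictly increasing.
        Defaults to a 1-second frame interval starting at 0.
    te:
        Echo time in seconds.  Only needed when converting signal to
        contrast-agent concentration.
    """

    data: np.ndarray
    grid_shape: tuple[int, int]
    frame_times: np.ndarray | None = None
    te: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (T x P), got shape {self.data.shape}")
        t, p = self.data.shape
        if t < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        if p < 1:
            raise ValueError("a dynamic series needs at least 1 pixel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        rows, cols = self.grid_shape
        if rows * cols != p:
            raise ValueError(
                f"grid_shape {self.grid_shape} incompatible with P={p} pixels"
            )
        self.grid_shape = (int(rows), int(cols))
        if self.frame_times is None:
            self.frame_times = np.arange(t, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (t,):
            raise ValueError("frame_times must have one entry per frame")
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.te is not None and self.te <= 0:
            raise ValueError("te must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_interval(self) -> float:
        """Mean frame spacing in seconds."""
        return float(np.mean(np.diff(self.frame_times)))

    def frame(self, t: int) -> np.ndarray:
        """Return frame ``t`` reshaped to the image grid."""
        return self.data[t].reshape(self.grid_shape)

    @classmethod
    def from_volume(
        cls,
        volume: np.ndarray,
        frame_times: np.ndarray | None = None,
        te: float | None = None,
    ) -> "DynamicSeries":
        """Build a series from a (rows, cols, T) or (T, rows, cols) stack.

        A 3-D array with the time axis last (the NIfTI convention for a
        single-slice dynamic scan) or first (the multi-page TIFF convention)
        is flattened to T x P.  The time axis is taken to be the last axis
        unless the array is explicitly (T, rows, cols) with T smaller than
        both spatial dimensions -- pass a pre-shaped matrix to be unambiguous.
        """
        volume = np.asarray(volume, dtype=float)
        if volume.ndim != 3:
            raise ValueError("expected a 3-D stack")
        if volume.shape[0] < min(volume.shape[1], volume.shape[2]):
            t_axis_first = True
        else:
            t_axis_first = False
        if t_axis_first:
            t, rows, cols = volume.shape
            data = volume.reshape(t, rows * cols)
        else:
            rows, cols, t = volume.shape
            data = np.moveaxis(volume, -1, 0).reshape(t, rows * cols)
        return cls(data=data, grid_shape=(rows, cols), frame_times=frame_times, te=te)
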