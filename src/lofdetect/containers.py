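"""Core in-memory containers.

A recording is held channel-major: a ``(n_channels, n_samples)`` float array in
microvolts, a sampling rate in Hz, and one unique label per channel.  Every
algorithm in the package treats each channel's full time series as one point
in an ``n_samples``-dimensional activity space; electrode scalp positions play
no role anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["ChannelMatrix"]


@dataclass
class ChannelMatrix:
    """Multichannel continuous EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts, float64, no missing values.
    srate : float
        Sampling rate in samples/second, > 0.
    labels : list of str
        Unique channel names, one per row of ``data``.
    """

    data: np.ndarray
    srate: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ParameterError("data must be 2-D (n_channels, n_samples)")
        n_channels, n_samples = self.data.shape
        if n_channels < 2:
            raise ParameterError("need at least 2 channels")
        if n_samples < 1:
            raise ParameterError("need at least 1 sample")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data contains NaN or infinite values")
        if not self.srate > 0:
            raise ParameterError("srate must be positive")
        self.srate = float(self.srate)
        if not self.labels:
            width = len(str(n_channels))
            self.labels = [f"E{i + 1:0{width}d}" for i in range(n_channels)]
        self.labels = [str(lb) for lb in self.labels]
        if len(self.labels) != n_channels:
            raise ParameterError("labels length must equal n_channels")
        if len(set(self.labels)) != n_channels:
            raise ParameterError("labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def subset(self, idx) -> "ChannelMatrix":
        """Return a new ChannelMatrix restricted to channel indices ``idx``."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ChannelMatrix(
            data=self.data[idx].copy(),
            srate=self.srate,
            labels=[self.labels[i] for i in idx],
        )
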