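"""End-to-end bad-channel detection.

Pipeline: optional zero-phase FIR band filtering, flat-line pre-detection,
LOF scoring of the remaining channels, and thresholding.  Flat channels are
excluded from the LOF channel set before scoring: identical flat vectors are
zero-distance duplicates that distort both the standardized-euclidean scale
and the local densities, and their badness is already established.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.signal import fftconvolve, firwin, kaiserord

from .containers import ChannelMatrix
from .errors import InsufficientChannelsError, LowDensityWarning, ParameterError
from .lof import DistanceSpec, LOFScores, lof_scores

__all__ = [
    "FilterSpec",
    "DetectionResult",
    "apply_filters",
    "detect_flatlines",
    "classify_by_threshold",
    "detect_bad_channels",
]

#: Montage sizes below this trigger a LowDensityWarning: the local-density
#: approach needs enough channels to define meaningful neighborhoods.
MIN_RECOMMENDED_CHANNELS = 32

#: Default tolerance for "constant value": exact flat lines up to float
#: noise.  Raise it for real recordings with quantization jitter.
DEFAULT_FLAT_TOLERANCE_UV = 1e-8


@dataclass
class FilterSpec:
    """Zero-phase FIR band filtering parameters.

    lowpass_cutoff : float or None
        Low-pass cutoff in Hz (half-amplitude point; fixed 5 Hz transition).
    highpass_transition_band : (low, high) in Hz or None
        High-pass transition band; the half-amplitude cutoff sits at its
        midpoint.
    stopband_attenuation : float
        Kaiser-design stop-band attenuation in dB.
    """

    lowpass_cutoff: Optional[float] = 40.0
    highpass_transition_band: Optional[tuple[float, float]] = (0.1, 0.35)
    stopband_attenuation: float = 80.0

    def __post_init__(self) -> None:
        if self.highpass_transition_band is not None:
            lo, hi = self.highpass_transition_band
            if not 0 <= lo < hi:
                raise ParameterError("highpass transition band must be strictly increasing")
            self.highpass_transition_band = (float(lo), float(hi))
        if self.stopband_attenuation <= 0:
            raise ParameterError("stopband_attenuation must be positive")


@dataclass
class DetectionResult:
    """Boolean bad flags with per-detector provenance.

    Invariant: ``bad_flags == flatline_flags | (lof > threshold_used)``
    channel-wise (flat channels carry NaN LOF and count via the flat flag).
    Provenance is ``"flatline"`` or ``"lof"`` per flagged channel; flatline
    wins when both apply.
    """

    bad_flags: np.ndarray
    lof: np.ndarray  # NaN for channels excluded as flat
    flatline_flags: np.ndarray
    threshold_used: float
    k_used: int
    metric_used: DistanceSpec
    labels: list[str] = field(default_factory=list)

    @property
    def provenance(self) -> dict[str, str]:
        out = {}
        for i, bad in enumerate(self.bad_flags):
            if not bad:
                continue
            name = self.labels[i] if self.labels else str(i)
            out[name] = "flatline" if self.flatline_flags[i] else "lof"
        return out

    @property
    def bad_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bad_flags)

    @property
    def bad_labels(self) -> list[str]:
        return [self.labels[i] for i in self.bad_indices] if self.labels else []


def _kaiser_taps(cutoff_hz, width_hz, srate, atten_db, pass_zero):
    nyq = srate / 2.0
    numtaps, beta = kaiserord(atten_db, width_hz / nyq)
    numtaps |= 1  # odd length -> type-I linear phase, integer group delay
    return firwin(numtaps, cutoff_hz, window=("kaiser", beta), pass_zero=pass_zero, fs=srate)


def _fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with delay compensation (zero net phase)."""
    pad = taps.size // 2
    if data.shape[1] <= pad:
        raise ParameterError(
            f"recording too short ({data.shape[1]} samples) for a "
            f"{taps.size}-tap filter"
        )
    padded = np.pad(data, ((0, 0), (pad, pad)), mode="reflect")
    out = fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, pad:-pad]


def apply_filters(X: ChannelMatrix, f: FilterSpec) -> ChannelMatrix:
    """Zero-phase FIR filtering (low-pass and/or high-pass)."""
    nyq = X.srate / 2.0
    data = X.data
    if f.lowpass_cutoff is not None:
        if f.lowpass_cutoff >= nyq:
            raise ParameterError(f"low-pass cutoff {f.lowpass_cutoff} Hz >= Nyquist {nyq} Hz")
        width = min(5.0, nyq - f.lowpass_cutoff)
        # place the half-amplitude point so the stop band starts at cutoff+width
        taps = _kaiser_taps(f.lowpass_cutoff + width / 2.0, width, X.srate,
                            f.stopband_attenuation, pass_zero=True)
        data = _fir_zero_phase(data, taps)
    if f.highpass_transition_band is not None:
        lo, hi = f.highpass_transition_band
        if hi >= nyq:
            raise ParameterError(f"high-pass band edge {hi} Hz >= Nyquist {nyq} Hz")
        taps = _kaiser_taps((lo + hi) / 2.0, hi - lo, X.srate,
                            f.stopband_attenuation, pass_zero=False)
        data = _fir_zero_phase(data, taps)
    return ChannelMatrix(data=data, srate=X.srate, labels=list(X.labels))


def detect_flatlines(
    X: ChannelMatrix,
    min_duration_s: float = 5.0,
    tolerance_uV: float = DEFAULT_FLAT_TOLERANCE_UV,
) -> np.ndarray:
    """Flag channels holding a constant value for at least ``min_duration_s``.

    A channel is flagged when it contains a contiguous run of at least
    ``min_duration_s * srate`` successive-sample differences whose absolute
    value is <= ``tolerance_uV``.
    """
    min_run = int(np.ceil(min_duration_s * X.srate))
    if min_run < 2:
        raise ParameterError("min_duration_s x srate must cover at least 2 samples")
    small = np.abs(np.diff(X.data, axis=1)) <= tolerance_uV
    flags = np.zeros(X.n_channels, dtype=bool)
    for c in range(X.n_channels):
        run = small[c].astype(np.int8)
        if not run.any():
            continue
        # longest run of ones: reset cumulative count at each zero
        edges = np.diff(np.concatenate(([0], run, [0])))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        if (stops - starts).max() >= min_run:
            flags[c] = True
    return flags


def classify_by_threshold(scores: Union[LOFScores, np.ndarray], lof_thr: float) -> np.ndarray:
    """Flag channels whose LOF strictly exceeds ``lof_thr`` (NaN never flags)."""
    if lof_thr <= 0:
        raise ParameterError("lof_thr must be positive")
    lof = scores.lof if isinstance(scores, LOFScores) else np.asarray(scores, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.greater(lof, lof_thr, where=~np.isnan(lof), out=np.zeros(lof.shape, bool))


def detect_bad_channels(
    X: ChannelMatrix,
    spec: Optional[DistanceSpec] = None,
    lof_thr: float = 2.5,
    k: Union[int, str] = "auto",
    flatline: bool = True,
    filters: Optional[FilterSpec] = None,
    flat_min_duration_s: float = 5.0,
    flat_tolerance_uV: float = DEFAULT_FLAT_TOLERANCE_UV,
) -> DetectionResult:
    """Run the full detector and return labeled flags.

    Flat-line channels are flagged first and excluded from the LOF channel
    set; LOF flags (score > ``lof_thr``) are unioned with them.  Filtering is
    off by default — apply it explicitly (or via the CLI) when the data need
    band limiting.
    """
    if spec is None:
        spec = DistanceSpec()
    if X.n_channels < 3:
        raise InsufficientChannelsError(f"need >= 3 channels, got {X.n_channels}")
    if X.n_channels < MIN_RECOMMENDED_CHANNELS:
        warnings.warn(
            f"{X.n_channels} channels: the local-density approach is not "
            f"recommended below {MIN_RECOMMENDED_CHANNELS} channels",
            LowDensityWarning,
            stacklevel=2,
        )
    if filters is not None:
        X = apply_filters(X, filters)
    if flatline:
        flat_flags = detect_flatlines(X, flat_min_duration_s, flat_tolerance_uV)
    else:
        flat_flags = np.zeros(X.n_channels, dtype=bool)
    keep = np.flatnonzero(~flat_flags)
    if keep.size < 3:
        raise InsufficientChannelsError(
            f"only {keep.size} non-flat channels remain; need >= 3"
        )
    scores = lof_scores(X.subset(keep), spec, k)
    lof_full = np.full(X.n_channels, np.nan)
    lof_full[keep] = scores.lof
    lof_flags = classify_by_threshold(lof_full, lof_thr)
    return DetectionResult(
        bad_flags=flat_flags | lof_flags,
        lof=lof_full,
        flatline_flags=flat_flags,
        threshold_used=float(lof_thr),
        k_used=scores.k_used,
        metric_used=spec,
        labels=list(X.labels),
    )
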