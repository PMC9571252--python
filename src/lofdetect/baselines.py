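"""Comparison bad-channel detectors and per-channel statistical measures.

These re-implement, at the bad-CHANNEL stage only, the detectors commonly
used in EEG preprocessing pipelines:

* simple per-channel measures (mean amplitude, IQR, MAD, variance, ...)
  usable as threshold-sweep scores;
* a kurtosis z-score detector (z > 5 across channels);
* a FASTER-style detector (inter-channel correlation, variance, Hurst
  exponent, each z-scored, |z| > 3 on any feature);
* a clean-raw-data-style (CRD) detector: flat lines, line-noise power
  ratio, and windowed low spatial correlation;
* a HAPPE-style detector: joint outlyingness of average log spectral power
  over 1-125 Hz, 3 SD, applied twice.

All detectors are deterministic and permutation-equivariant over channels.
Channels with zero variance yield undefined values for variance-normalized
features (kurtosis, correlation, Hurst); they are excluded from the z-score
statistics and never flagged by those features — the flat-line detector is
the appropriate tool for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import welch

from .containers import ChannelMatrix
from .detect import detect_flatlines
from .errors import InsufficientChannelsError, ParameterError

__all__ = [
    "MeasureVector",
    "minmax_normalize",
    "channel_measures",
    "hurst_exponent",
    "kurtosis_detector",
    "faster_detector",
    "crd_detector",
    "happe_detector",
    "MEASURE_NAMES",
]

MEASURE_NAMES = ("mean", "iqr", "mad", "kurtosis", "variance", "correlation", "hurst", "logpower")


@dataclass
class MeasureVector:
    name: str
    values: np.ndarray
    normalized: bool = False


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map values affinely onto [0, 1] (constant input maps to all zeros)."""
    values = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def hurst_exponent(x: np.ndarray, n_scales: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent estimate.

    Window sizes are log-spaced between 10% and 50% of the series length;
    within each size the series is cut into non-overlapping segments, the
    range of the mean-adjusted cumulative sum is divided by the segment SD,
    and the log-log slope of the averaged R/S against the window size is the
    estimate (~0.5 for uncorrelated noise).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 20:
        raise ParameterError("series too short for R/S estimation")
    sizes = np.unique(np.geomspace(max(10, n // 10), n // 2, n_scales).astype(int))
    log_rs, log_w = [], []
    for w in sizes:
        n_seg = n // w
        segs = x[: n_seg * w].reshape(n_seg, w)
        centered = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(centered, axis=1)
        rng_ = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1, ddof=1)
        ok = sd > 0
        if not ok.any():
            continue
        rs = float(np.mean(rng_[ok] / sd[ok]))
        if rs > 0:
            log_rs.append(np.log(rs))
            log_w.append(np.log(w))
    if len(log_w) < 2:
        return np.nan
    slope = np.polyfit(log_w, log_rs, 1)[0]
    return float(slope)


def _mean_abs_correlation(data: np.ndarray) -> np.ndarray:
    """Per channel: mean |Pearson r| with every other channel (NaN if constant)."""
    sd = data.std(axis=1)
    ok = sd > 0
    out = np.full(data.shape[0], np.nan)
    if ok.sum() >= 2:
        r = np.corrcoef(data[ok])
        np.fill_diagonal(r, np.nan)
        out[ok] = np.nanmean(np.abs(r), axis=1)
    return out


def channel_measures(X: ChannelMatrix, name: str, normalized: bool = False) -> MeasureVector:
    """One per-channel scalar feature.

    ``iqr`` uses linear interpolation between order statistics for the
    25th/75th percentiles; ``mad`` is the median absolute deviation from the
    channel median; ``logpower`` is the average log10 Welch power over
    1-125 Hz (capped at Nyquist).
    """
    data = X.data
    if name == "mean":
        values = data.mean(axis=1)
    elif name == "iqr":
        q75, q25 = np.percentile(data, [75, 25], axis=1)
        values = q75 - q25
    elif name == "mad":
        values = np.median(np.abs(data - np.median(data, axis=1, keepdims=True)), axis=1)
    elif name == "variance":
        values = data.var(axis=1, ddof=1)
    elif name == "kurtosis":
        values = _safe_kurtosis(data)
    elif name == "correlation":
        values = _mean_abs_correlation(data)
    elif name == "hurst":
        values = np.array([hurst_exponent(row) if row.std() > 0 else np.nan for row in data])
    elif name == "logpower":
        values = _avg_log_power(X)
    else:
        raise ParameterError(f"unknown measure {name!r}; choose from {MEASURE_NAMES}")
    if normalized:
        values = minmax_normalize(values)
    return MeasureVector(name=name, values=values, normalized=normalized)


def _safe_kurtosis(data: np.ndarray) -> np.ndarray:
    sd = data.std(axis=1)
    values = np.full(data.shape[0], np.nan)
    ok = sd > 0
    if ok.any():
        values[ok] = stats.kurtosis(data[ok], axis=1, fisher=True, bias=True)
    return values


def _zscore_nan(values: np.ndarray) -> np.ndarray:
    """Z-score over the finite entries; non-finite entries stay NaN."""
    out = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        return out
    v = values[finite]
    sd = v.std()
    if sd == 0:
        out[finite] = 0.0
    else:
        out[finite] = (v - v.mean()) / sd
    return out


def kurtosis_detector(X: ChannelMatrix, z_cut: float = 5.0) -> np.ndarray:
    """Flag channels whose sample kurtosis z-score across channels exceeds ``z_cut``.

    One-sided: artifactual channels (spikes, steps) raise kurtosis.
    """
    if X.n_channels < 3:
        raise InsufficientChannelsError("kurtosis detector needs >= 3 channels")
    z = _zscore_nan(_safe_kurtosis(X.data))
    with np.errstate(invalid="ignore"):
        return np.greater(z, z_cut, where=np.isfinite(z), out=np.zeros(z.shape, bool))


def faster_detector(X: ChannelMatrix, z_cut: float = 3.0) -> np.ndarray:
    """FASTER-style flags: any of {correlation, variance, Hurst} beyond |z| > z_cut."""
    if X.n_channels < 3:
        raise InsufficientChannelsError("FASTER detector needs >= 3 channels")
    feats = [
        _mean_abs_correlation(X.data),
        X.data.var(axis=1, ddof=1),
        np.array([hurst_exponent(row) if row.std() > 0 else np.nan for row in X.data]),
    ]
    flags = np.zeros(X.n_channels, dtype=bool)
    for f in feats:
        z = _zscore_nan(f)
        with np.errstate(invalid="ignore"):
            flags |= np.greater(np.abs(z), z_cut, where=np.isfinite(z), out=np.zeros(z.shape, bool))
    return flags


def _windowed_max_correlation(data: np.ndarray, srate: float, window_s: float) -> np.ndarray:
    """Per channel: fraction of time windows whose max |r| with any other
    channel falls below the caller's cutoff is computed by the caller; this
    returns the (n_windows, n_channels) matrix of per-window max |r|."""
    n_ch, n_samp = data.shape
    win = max(2, int(round(window_s * srate)))
    n_win = n_samp // win
    out = np.zeros((n_win, n_ch))
    for w in range(n_win):
        seg = data[:, w * win : (w + 1) * win]
        sd = seg.std(axis=1)
        ok = sd > 0
        maxr = np.zeros(n_ch)
        if ok.sum() >= 2:
            r = np.corrcoef(seg[ok])
            np.fill_diagonal(r, 0.0)
            maxr[ok] = np.nanmax(np.abs(r), axis=1)
        out[w] = maxr
    return out


def crd_detector(
    X: ChannelMatrix,
    flat_s: float = 5.0,
    corr_cut: float = 0.8,
    broken_fraction: float = 0.4,
    line_freq: float = 50.0,
    line_z: float = 4.0,
    window_s: float = 5.0,
) -> np.ndarray:
    """Clean-raw-data-style detector: flat lines, line noise, low correlation.

    * flat line: constant for >= ``flat_s`` seconds;
    * line noise: z-score (across channels) of the power ratio in
      ``line_freq`` +- 1 Hz over broadband power exceeds ``line_z``
      (skipped when the band is above Nyquist);
    * correlation: in ``window_s``-second windows, the channel's max |r|
      with any other channel falls below ``corr_cut`` in more than
      ``broken_fraction`` of windows.
    """
    if X.n_channels < 3:
        raise InsufficientChannelsError("CRD detector needs >= 3 channels")
    flags = detect_flatlines(X, min_duration_s=flat_s)

    nyq = X.srate / 2.0
    if line_freq + 1.0 < nyq:
        nperseg = min(X.n_samples, int(4 * X.srate))
        freqs, psd = welch(X.data, fs=X.srate, nperseg=nperseg, axis=1)
        band = (freqs >= line_freq - 1.0) & (freqs <= line_freq + 1.0)
        total = psd.sum(axis=1)
        ok = total > 0
        ratio = np.full(X.n_channels, np.nan)
        ratio[ok] = psd[ok][:, band].sum(axis=1) / total[ok]
        z = _zscore_nan(ratio)
        with np.errstate(invalid="ignore"):
            flags |= np.greater(z, line_z, where=np.isfinite(z), out=np.zeros(z.shape, bool))

    maxr = _windowed_max_correlation(X.data, X.srate, window_s)
    if maxr.shape[0] > 0:
        broken = (maxr < corr_cut).mean(axis=0)
        flags |= broken > broken_fraction
    return flags


def _avg_log_power(X: ChannelMatrix, f_lo: float = 1.0, f_hi: float = 125.0) -> np.ndarray:
    """Average log10 Welch power per channel over [f_lo, min(f_hi, Nyquist)).

    1-second windows with 50% overlap; powers floored at 1e-12 x the median
    positive power so exactly-flat channels appear as huge (finite) low
    outliers instead of -inf.
    """
    nperseg = min(X.n_samples, max(8, int(round(X.srate))))
    freqs, psd = welch(X.data, fs=X.srate, nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    hi = min(f_hi, X.srate / 2.0 * 0.999)
    band = (freqs >= f_lo) & (freqs <= hi)
    if not band.any():
        raise ParameterError("no spectral bins in the requested band")
    p = psd[:, band]
    positive = p[p > 0]
    floor = 1e-12 * (np.median(positive) if positive.size else 1.0)
    return np.log10(np.maximum(p, floor)).mean(axis=1)


def happe_detector(X: ChannelMatrix, sd_cut: float = 3.0, passes: int = 2) -> np.ndarray:
    """HAPPE-style flags: average log power outliers, computed ``passes`` times.

    Channels whose average log power over 1-125 Hz deviates more than
    ``sd_cut`` standard deviations from the cross-channel mean are flagged;
    flagged channels are removed and the statistics recomputed; the union of
    flags over passes is returned.
    """
    if X.n_channels < 3:
        raise InsufficientChannelsError("HAPPE detector needs >= 3 channels")
    logp = _avg_log_power(X)
    flags = np.zeros(X.n_channels, dtype=bool)
    for _ in range(passes):
        active = ~flags
        if active.sum() < 3:
            break
        v = logp[active]
        sd = v.std()
        if sd == 0:
            break
        new = np.zeros_like(flags)
        new[active] = np.abs(v - v.mean()) > sd_cut * sd
        if not new.any():
            break
        flags |= new
    return flags
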