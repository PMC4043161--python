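"""Signal conditioning and two-dimensional attractor reconstruction.

A scalar signal is turned into planar phase portraits in sliding windows,
either by delay embedding (plotting the signal against a delayed copy of
itself) or via the analytic signal (real part against imaginary part of the
Hilbert transform).  The embedding delay is chosen from the data: the first
zero crossing of the autocorrelation function, or the first minimum of the
lagged mutual information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.signal.windows import tukey

from .types import (
    InvalidParameterError,
    PhasegramError,
    PhasePortrait,
    SignalTooShortError,
    TimeSeries,
)


class DelaySelectionError(PhasegramError, RuntimeError):
    """No suitable embedding delay found within the search bound."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """How phase portraits are reconstructed from the signal.

    Parameters
    ----------
    method : {"delay-autocorr", "delay-mutualinfo", "fixed-delay", "hilbert"}
        Delay methods plot (x[j], x[j+n]); "hilbert" plots the analytic
        signal's real part against its imaginary part.
    delay_n : int or None
        Embedding delay in samples (required for "fixed-delay"; filled in
        by :func:`resolve_delay` for the automatic methods).
    half_window_m : int or None
        Half window length m in samples; a window holds 2m+1 samples.
        ``None`` derives it from ``window_s`` at resolve time.
    window_s : float
        Window length in seconds used when ``half_window_m`` is None.
    hop_s : float
        Interval between consecutive window centres (strip interval).
    max_delay_s : float
        Search bound for the automatic delay estimators.
    mi_bins : int
        Histogram bins per axis for the mutual-information estimator.
    """

    method: str = "delay-autocorr"
    delay_n: int | None = None
    half_window_m: int | None = None
    window_s: float = 0.2
    hop_s: float = 0.02
    max_delay_s: float = 0.1
    mi_bins: int = 16

    _METHODS = ("delay-autocorr", "delay-mutualinfo", "fixed-delay", "hilbert")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise InvalidParameterError(
                f"unknown embedding method {self.method!r}"
            )
        if self.method == "fixed-delay" and (self.delay_n is None
                                             or self.delay_n < 1):
            raise InvalidParameterError("fixed-delay needs delay_n >= 1")
        if self.delay_n is not None and self.delay_n < 1:
            raise InvalidParameterError("delay_n must be >= 1")
        if self.hop_s <= 0:
            raise InvalidParameterError("hop_s must be > 0")
        if self.half_window_m is not None and self.delay_n is not None \
                and self.half_window_m < self.delay_n:
            raise InvalidParameterError("half_window_m must be >= delay_n")


def remove_dc(ts: TimeSeries) -> TimeSeries:
    """Subtract the signal mean."""
    return ts.replace(samples=ts.samples - ts.samples.mean())


def highpass(ts: TimeSeries, cutoff_hz: float, order: int = 2) -> TimeSeries:
    """Zero-phase (forward-backward Butterworth) high-pass filter.

    Used against slow baseline drift; phase preservation matters because
    portrait geometry is phase-sensitive.
    """
    if cutoff_hz >= ts.fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({ts.fs / 2} Hz)"
        )
    sos = butter(order, cutoff_hz, btype="highpass", fs=ts.fs, output="sos")
    return ts.replace(samples=sosfiltfilt(sos, ts.samples))


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation for lags 0..max_lag, via FFT."""
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec))[: max_lag + 1]
    if acf[0] == 0:
        raise InvalidParameterError("constant signal has no autocorrelation")
    return acf / acf[0]


def estimate_delay_autocorr(ts: TimeSeries, max_delay_s: float = 0.1) -> int:
    """Delay at the autocorrelation function's first zero crossing.

    The crossing is located by linear interpolation between the last
    positive and first non-positive lag, rounded to the nearer integer lag
    (minimum 1).
    """
    max_lag = min(int(round(max_delay_s * ts.fs)), len(ts) - 1)
    if max_lag < 1:
        raise InvalidParameterError("max_delay_s shorter than one sample")
    acf = _autocorrelation(ts.samples, max_lag)
    sign_change = np.flatnonzero((acf[:-1] > 0) & (acf[1:] <= 0))
    if sign_change.size == 0:
        raise DelaySelectionError(
            f"autocorrelation has no zero crossing within {max_delay_s} s"
        )
    k = int(sign_change[0])
    frac = acf[k] / (acf[k] - acf[k + 1])
    return max(1, int(round(k + frac)))


def lagged_mutual_information(x: np.ndarray, lag: int, n_bins: int) -> float:
    """Histogram estimate of I(x[i]; x[i+lag]) in nats."""
    a, b = x[:-lag], x[lag:]
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def estimate_delay_mutualinfo(ts: TimeSeries, max_delay_s: float = 0.1,
                              n_bins: int = 16) -> int:
    """Delay at the first strict local minimum of lagged mutual information."""
    if n_bins < 4:
        raise InvalidParameterError("n_bins must be >= 4")
    if np.ptp(ts.samples) == 0:
        raise InvalidParameterError("constant signal carries no information")
    max_lag = min(int(round(max_delay_s * ts.fs)), len(ts) - 2)
    if max_lag < 2:
        raise InvalidParameterError("max_delay_s shorter than two samples")
    mi = np.array([lagged_mutual_information(ts.samples, lag, n_bins)
                   for lag in range(1, max_lag + 1)])
    interior = np.flatnonzero((mi[1:-1] < mi[:-2]) & (mi[1:-1] < mi[2:]))
    if interior.size == 0:
        raise DelaySelectionError(
            f"mutual information has no interior minimum within {max_delay_s} s"
        )
    return int(interior[0]) + 2   # +1 for the diff offset, +1 for lag base


def resolve_delay(ts: TimeSeries, cfg: EmbeddingConfig) -> int:
    """Embedding delay for the whole signal, per the configured method.

    The delay is computed once globally (not per window) so the portrait
    axes stay comparable across the phasegram.  The autocorrelation method
    falls back to mutual information when no zero crossing exists.
    """
    if cfg.method == "hilbert":
        return 0
    if cfg.method == "fixed-delay" or cfg.delay_n is not None:
        return int(cfg.delay_n)
    if np.ptp(ts.samples) == 0.0:
        return 1     # constant signal: any delay gives a single-point portrait
    if cfg.method == "delay-autocorr":
        try:
            return estimate_delay_autocorr(ts, cfg.max_delay_s)
        except DelaySelectionError:
            return estimate_delay_mutualinfo(ts, cfg.max_delay_s, cfg.mi_bins)
    return estimate_delay_mutualinfo(ts, cfg.max_delay_s, cfg.mi_bins)


def resolve_config(ts: TimeSeries, cfg: EmbeddingConfig) -> EmbeddingConfig:
    """Fill in delay_n and half_window_m from the signal."""
    n = resolve_delay(ts, cfg)
    m = cfg.half_window_m
    if m is None:
        m = max(1, int(round(cfg.window_s * ts.fs)) // 2)
    if cfg.method != "hilbert":
        m = max(m, n)
    return replace(cfg, delay_n=n if n > 0 else cfg.delay_n,
                   half_window_m=m)


def delay_embed(ts: TimeSeries, center_i: int,
                cfg: EmbeddingConfig) -> PhasePortrait:
    """Portrait of (x[j], x[j+n]) over the window centred at ``center_i``.

    The window is [center_i - m, center_i + m]; the portrait has
    2m + 1 - n points so both coordinates stay inside the window.
    """
    n = cfg.delay_n
    m = cfg.half_window_m
    if n is None or m is None:
        raise InvalidParameterError("config not resolved: delay_n/half_window_m")
    lo, hi = center_i - m, center_i + m
    if lo < 0 or hi >= len(ts):
        raise SignalTooShortError(
            f"window [{lo}, {hi}] out of range for signal of {len(ts)}"
        )
    x = ts.samples
    u = x[lo: hi - n + 1]
    v = x[lo + n: hi + 1]
    return PhasePortrait(np.column_stack([u, v]), center_i / ts.fs, (lo, hi))


#: Fraction of the window tapered (and excluded) at each edge for the
#: Hilbert embedding, limiting transform edge effects.
HILBERT_EDGE_FRACTION = 0.10


def hilbert_embed(ts: TimeSeries, center_i: int,
                  cfg: EmbeddingConfig) -> PhasePortrait:
    """Portrait of the analytic signal (real, imag) over one window.

    The window is cosine-tapered (Tukey, 10% per edge) before the
    transform and the first/last 10% of points are dropped: the analytic
    signal of a finite window is unreliable near its edges, and the
    fractional-cycle leakage of an untapered window distorts the whole
    portrait.  The mean is removed after tapering so no spurious DC leaks
    into the real coordinate.
    """
    m = cfg.half_window_m
    if m is None:
        raise InvalidParameterError("config not resolved: half_window_m")
    lo, hi = center_i - m, center_i + m
    if lo < 0 or hi >= len(ts):
        raise SignalTooShortError(
            f"window [{lo}, {hi}] out of range for signal of {len(ts)}"
        )
    w = ts.samples[lo: hi + 1]
    tapered = w * tukey(w.size, alpha=2 * HILBERT_EDGE_FRACTION)
    tapered = tapered - tapered.mean()
    analytic = hilbert(tapered)
    edge = max(1, int(round(HILBERT_EDGE_FRACTION * w.size)))
    core = analytic[edge:-edge]
    return PhasePortrait(np.column_stack([core.real, core.imag]),
                         center_i / ts.fs, (lo, hi))


def embed(ts: TimeSeries, center_i: int, cfg: EmbeddingConfig) -> PhasePortrait:
    """Dispatch to the configured embedding."""
    if cfg.method == "hilbert":
        return hilbert_embed(ts, center_i, cfg)
    return delay_embed(ts, center_i, cfg)


def window_centers(ts: TimeSeries, cfg: EmbeddingConfig) -> np.ndarray:
    """Sample indices of consecutive window centres.

    Centres start at the first index with a full window, advance by
    round(fs * hop_s), and stop at the last index where the window (plus
    the embedding delay, for delay methods) stays inside the signal.
    """
    m = cfg.half_window_m
    if m is None:
        raise InvalidParameterError("config not resolved: half_window_m")
    n = cfg.delay_n if (cfg.method != "hilbert" and cfg.delay_n) else 0
    first = m
    last = len(ts) - 1 - m - n
    if last < first:
        raise SignalTooShortError(
            f"signal of {len(ts)} samples shorter than one window (2m+1+n = "
            f"{2 * m + 1 + n})"
        )
    step = max(1, int(round(ts.fs * cfg.hop_s)))
    return np.arange(first, last + 1, step)
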