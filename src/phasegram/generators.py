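"""Synthetic test signals with known dynamics.

Three families are provided, all deterministic and seedable:

* a logistic-map parameter sweep, the textbook period-doubling cascade,
  rendered audible by band-limited (sinc) upsampling;
* a Lorenz-system parameter sweep integrated as difference equations and
  replayed at audio rate;
* phase-randomized surrogates, which keep a signal's amplitude spectrum but
  destroy its deterministic phase structure.

Plus small fixtures (:func:`gen_sine`) and shared conditioning
(:func:`normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    InvalidParameterError,
    NumericDomainError,
    TimeSeries,
)

#: Half-width of the windowed-sinc interpolation kernel, in input samples.
SINC_KERNEL_HALF_WIDTH = 32


@dataclass(frozen=True)
class LogisticSweepSpec:
    """Configuration of a logistic-map parameter sweep.

    The map ``x[i+1] = a x[i] (1 - x[i])`` is iterated once per sample at
    ``base_fs`` while ``a`` moves linearly from ``a_start`` to ``a_end``;
    the centred, normalized orbit is then sinc-upsampled to ``target_fs``.
    """

    a_start: float = 3.4
    a_end: float = 3.65
    duration_s: float = 10.0
    base_fs: float = 1000.0
    x0: float = 0.5
    target_fs: float = 44100.0

    def __post_init__(self) -> None:
        for a in (self.a_start, self.a_end):
            if not 0.0 < a <= 4.0:
                raise InvalidParameterError(
                    f"map parameter must stay in (0, 4], got {a}"
                )
        if self.base_fs <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("base_fs and duration_s must be > 0")
        if self.target_fs < self.base_fs:
            raise InvalidParameterError("target_fs must be >= base_fs")
        if not 0.0 < self.x0 < 1.0:
            raise InvalidParameterError(f"x0 must lie in (0, 1), got {self.x0}")


@dataclass(frozen=True)
class LorenzSweepSpec:
    """Configuration of a Lorenz-system parameter sweep.

    The system is integrated as explicit difference equations with step
    ``dt`` while r moves linearly from ``r_start`` to ``r_end`` over
    ``sweep_samples`` steps, then holds for ``hold_samples`` steps.  The
    sample train is replayed ("sped up") at ``playback_fs``.
    """

    sigma: float = 10.0
    b: float = 8.0 / 3.0
    r_start: float = 250.0
    r_end: float = 28.0
    sweep_samples: int = 308_700      # 7 s of playback at 44.1 kHz
    hold_samples: int = 132_300       # 3 s of playback at 44.1 kHz
    dt: float = 1.0 / 882.0
    playback_fs: float = 44100.0
    init: tuple[float, float, float] = (0.0, 20.0, 25.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.sweep_samples + self.hold_samples <= 0:
            raise InvalidParameterError("need at least one integration step")
        if self.playback_fs <= 0:
            raise InvalidParameterError("playback_fs must be > 0")


def logistic_orbit(spec: LogisticSweepSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw map iterates and the per-sample parameter track.

    Returns ``(x, a)`` where ``x[0] = x0`` and
    ``x[i+1] = a[i] x[i] (1 - x[i])``.  All samples are kept; no transient
    is discarded.
    """
    n = int(round(spec.duration_s * spec.base_fs))
    a = np.linspace(spec.a_start, spec.a_end, n)
    x = np.empty(n)
    x[0] = spec.x0
    for i in range(n - 1):
        x[i + 1] = a[i] * x[i] * (1.0 - x[i])
    if np.any(x < 0.0) or np.any(x > 1.0):
        bad = int(np.argmax((x < 0.0) | (x > 1.0)))
        raise NumericDomainError(
            f"logistic iterate left [0, 1] at sample {bad}"
        )
    return x, a


def gen_logistic(spec: LogisticSweepSpec) -> TimeSeries:
    """Centred, normalized, sinc-upsampled logistic-map sweep."""
    x, _ = logistic_orbit(spec)
    base = TimeSeries(x, spec.base_fs, label="logistic sweep")
    conditioned = normalize(base)
    if spec.target_fs == spec.base_fs:
        return conditioned
    return sinc_upsample(conditioned, spec.target_fs)


def sinc_upsample(ts: TimeSeries, target_fs: float) -> TimeSeries:
    """Band-limited upsampling with a Hann-windowed sinc kernel.

    The kernel half-width is :data:`SINC_KERNEL_HALF_WIDTH` input samples;
    samples outside the input are treated as zero, so a few edge samples
    deviate from the ideal band-limited reconstruction.
    """
    if target_fs < ts.fs:
        raise InvalidParameterError(
            f"downsampling unsupported: target_fs {target_fs} < fs {ts.fs}"
        )
    if target_fs == ts.fs:
        return ts.replace()
    x = ts.samples
    n_in = x.size
    n_out = int(round(n_in * target_fs / ts.fs))
    half = SINC_KERNEL_HALF_WIDTH
    out = np.empty(n_out)
    # chunked evaluation keeps the (chunk x taps) work array small
    chunk = 65536
    taps = np.arange(-half + 1, half + 1)
    for lo in range(0, n_out, chunk):
        hi = min(lo + chunk, n_out)
        u = np.arange(lo, hi) * (ts.fs / target_fs)   # position in input samples
        j0 = np.floor(u).astype(np.int64)
        j = j0[:, None] + taps[None, :]
        d = u[:, None] - j                            # |d| <= half
        w = 0.5 * (1.0 + np.cos(np.pi * d / half))
        k = np.sinc(d) * w
        xj = np.where((j >= 0) & (j < n_in), x[np.clip(j, 0, n_in - 1)], 0.0)
        out[lo:hi] = np.einsum("ij,ij->i", xj, k)
    return TimeSeries(out, target_fs, label=ts.label)


def gen_lorenz(spec: LorenzSweepSpec) -> TimeSeries:
    """x-component of a swept Lorenz system, centred and normalized.

    Explicit-Euler difference equations at step ``spec.dt``; the resulting
    sample train (initial state plus one sample per step) is reinterpreted
    at ``spec.playback_fs``, i.e. replayed faster than simulated.
    """
    sigma, b, dt = spec.sigma, spec.b, spec.dt
    n_steps = spec.sweep_samples + spec.hold_samples
    r_track = np.empty(n_steps)
    r_track[: spec.sweep_samples] = np.linspace(
        spec.r_start, spec.r_end, spec.sweep_samples
    )
    r_track[spec.sweep_samples:] = spec.r_end
    x, y, z = spec.init
    xs = np.empty(n_steps + 1)
    xs[0] = x
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_steps):
            r = r_track[i]
            dx = sigma * (y - x)
            dy = x * (r - z) - y
            dz = x * y - b * z
            x += dt * dx
            y += dt * dy
            z += dt * dz
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                raise NumericDomainError(
                    f"Lorenz integration blew up at sample {i + 1}"
                )
            xs[i + 1] = x
    ts = TimeSeries(xs, spec.playback_fs, label="lorenz sweep")
    return normalize(ts)


def phase_randomized_surrogate(ts: TimeSeries, seed: int) -> TimeSeries:
    """Surrogate with the same amplitude spectrum but random phases.

    Positive-frequency phases are drawn uniformly on [0, 2pi) from a seeded
    generator; DC and (for even length) the Nyquist bin keep zero phase so
    the inverse transform is exactly real.
    """
    if len(ts) < 4:
        raise InvalidParameterError("surrogate needs >= 4 samples")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(ts.samples)
    mags = np.abs(spec)
    phases = np.zeros_like(mags)
    n = len(ts)
    last = mags.size - 1 if n % 2 == 0 else mags.size  # exclude Nyquist bin
    phases[1:last] = rng.uniform(0.0, 2.0 * np.pi, size=last - 1)
    surrogate = np.fft.irfft(mags * np.exp(1j * phases), n=n)
    return TimeSeries(surrogate, ts.fs, label=f"{ts.label} surrogate".strip())


def gen_sine(freq: float, amp: float, duration_s: float, fs: float,
             phase: float = 0.0) -> TimeSeries:
    """Exact sampled sinusoid ``amp * sin(2 pi f t + phase)``."""
    if freq >= fs / 2:
        raise InvalidParameterError(
            f"freq {freq} Hz aliases at fs {fs} Hz (needs freq < fs/2)"
        )
    t = np.arange(int(round(duration_s * fs))) / fs
    return TimeSeries(amp * np.sin(2.0 * np.pi * freq * t + phase), fs,
                      label=f"sine {freq} Hz")


def normalize(ts: TimeSeries) -> TimeSeries:
    """Subtract the mean, then scale the peak absolute value to 1."""
    centred = ts.samples - ts.samples.mean()
    peak = np.abs(centred).max()
    if peak == 0.0:
        raise NumericDomainError("cannot normalize a constant signal")
    return ts.replace(samples=centred / peak)


def logistic_two_cycle(a: float) -> tuple[float, float]:
    """Analytic period-2 orbit of the logistic map, valid for 3 < a < 1+sqrt(6)."""
    disc = (a - 3.0) * (a + 1.0)
    if disc < 0:
        raise InvalidParameterError(f"no real two-cycle for a = {a}")
    root = np.sqrt(disc)
    return ((a + 1.0 - root) / (2.0 * a), (a + 1.0 + root) / (2.0 * a))
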