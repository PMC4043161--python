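"""Asymmetric two-mass model of vocal-fold vibration.

Each vocal fold is a pair of coupled damped oscillators (a lower and an
upper mass) driven by Bernoulli pressure on the lower mass while the glottis
is open, with extra restoring stiffness while the opposing folds collide.
Left-right asymmetry is introduced by a coefficient Q that scales the left
fold's masses (1/Q) and stiffnesses (Q), detuning its eigenfrequency - the
classic model for rough, subharmonic and chaotic phonation in asymmetric
(e.g. unilaterally paralyzed) larynges.

Internal units follow the model's convention: g, cm, ms; pressures in
g cm^-1 ms^-2 (1 such unit = 100 kPa).  The public API speaks seconds and
kPa and converts at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .types import (
    InvalidParameterError,
    NumericDomainError,
    PhasegramError,
    TimeSeries,
)

#: kPa per internal pressure unit (g cm^-1 ms^-2).
KPA_PER_INTERNAL = 100.0


class NoOnsetError(PhasegramError, RuntimeError):
    """The folds never sustained an oscillation above threshold."""


@dataclass(frozen=True)
class TwoMassParams:
    """Standard parameter set of the asymmetric two-mass model.

    Masses in g, stiffnesses in g/ms^2, geometry in cm.  ``q`` scales the
    left fold: masses divided by q, stiffnesses (including the coupling
    stiffness) multiplied by q, so the left eigenfrequencies scale by q.
    Collision adds stiffness ``collision_factor * k_i`` while the
    respective glottal area is closed.
    """

    m1: float = 0.125
    m2: float = 0.025
    k1: float = 0.08
    k2: float = 0.008
    kc: float = 0.025
    zeta1: float = 0.1
    zeta2: float = 0.6
    collision_factor: float = 3.0
    q: float = 1.0
    a01: float = 0.05          # rest glottal area at the lower masses, cm^2
    a02: float = 0.05          # rest glottal area at the upper masses, cm^2
    fold_length: float = 1.4   # cm
    d1: float = 0.25           # lower-mass thickness, cm
    d2: float = 0.05           # upper-mass thickness, cm

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise InvalidParameterError(f"q must lie in (0, 1], got {self.q}")
        for name in ("m1", "m2", "k1", "k2", "kc"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class PressureProfile:
    """Piecewise-linear subglottal (lung) pressure protocol in kPa."""

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        bp = tuple((float(t), float(p)) for t, p in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        times = [t for t, _ in bp]
        if len(bp) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError("breakpoint times must strictly increase")
        if any(p < 0 for _, p in bp):
            raise InvalidParameterError("pressures must be >= 0")

    def pressure_at(self, t_s: np.ndarray | float) -> np.ndarray | float:
        times = np.array([t for t, _ in self.breakpoints])
        vals = np.array([p for _, p in self.breakpoints])
        return np.interp(t_s, times, vals)

    @property
    def t_end(self) -> float:
        return self.breakpoints[-1][0]

    @classmethod
    def triangular(cls, peak_kpa: float = 2.5,
                   duration_s: float = 10.0) -> "PressureProfile":
        """Symmetric up-down ramp 0 -> peak -> 0 over the run."""
        return cls(((0.0, 0.0), (duration_s / 2.0, peak_kpa),
                    (duration_s, 0.0)))


def simulate(params: TwoMassParams, profile: PressureProfile,
             dt: float = 0.05e-3, duration_s: float = 10.0,
             return_upper: bool = False, x_init: float = 0.01):
    """Integrate the model; return lower-mass displacement traces.

    Explicit Euler at step ``dt`` (seconds; must be <= 0.1 ms for
    stability).  All four masses start displaced by ``x_init`` cm (the
    model's customary initial condition; the rest position is an exact
    equilibrium, so some perturbation is required for onset).  Returns
    ``(left, right)`` lower-mass displacement :class:`TimeSeries` at
    fs = 1/dt; with ``return_upper`` the upper-mass traces are appended,
    giving a 4-tuple.
    """
    if dt > 0.1e-3:
        raise InvalidParameterError("dt must be <= 0.1 ms for stability")
    if profile.t_end < duration_s:
        raise InvalidParameterError("pressure profile must cover the run")

    p = params
    q = p.q
    # right fold = standard, left fold = detuned by q
    m1r, m2r, k1r, k2r, kcr = p.m1, p.m2, p.k1, p.k2, p.kc
    m1l, m2l = p.m1 / q, p.m2 / q
    k1l, k2l, kcl = p.k1 * q, p.k2 * q, p.kc * q
    r1l = 2.0 * p.zeta1 * math.sqrt(m1l * k1l)
    r2l = 2.0 * p.zeta2 * math.sqrt(m2l * k2l)
    r1r = 2.0 * p.zeta1 * math.sqrt(m1r * k1r)
    r2r = 2.0 * p.zeta2 * math.sqrt(m2r * k2r)
    c1l, c2l = p.collision_factor * k1l, p.collision_factor * k2l
    c1r, c2r = p.collision_factor * k1r, p.collision_factor * k2r
    a01, a02, lg, d1 = p.a01, p.a02, p.fold_length, p.d1

    n = int(round(duration_s / dt))
    dt_ms = dt * 1e3
    ps_track = np.asarray(
        profile.pressure_at(np.arange(n) * dt)) / KPA_PER_INTERNAL

    x1l = x1r = x2l = x2r = x_init
    v1l = v1r = v2l = v2r = 0.0
    out_1l = np.empty(n)
    out_1r = np.empty(n)
    out_2l = np.empty(n) if return_upper else None
    out_2r = np.empty(n) if return_upper else None

    for i in range(n):
        ps = ps_track[i]
        a1 = a01 + lg * (x1l + x1r)
        a2 = a02 + lg * (x2l + x2r)
        # Bernoulli pressure on the lower masses while the glottis is open
        if a1 > 0.0:
            amin = a1 if a1 < a2 else a2
            if amin > 0.0:
                p1 = ps * (1.0 - (amin / a1) ** 2)
            else:
                p1 = ps
        else:
            p1 = 0.0
        f1 = p1 * lg * d1
        # collision restoring forces while an area is closed
        i1 = -c1l * (a1 / (2.0 * lg)) if a1 <= 0.0 else 0.0
        i1r_ = -c1r * (a1 / (2.0 * lg)) if a1 <= 0.0 else 0.0
        i2 = -c2l * (a2 / (2.0 * lg)) if a2 <= 0.0 else 0.0
        i2r_ = -c2r * (a2 / (2.0 * lg)) if a2 <= 0.0 else 0.0

        acc1l = (f1 + i1 - r1l * v1l - k1l * x1l - kcl * (x1l - x2l)) / m1l
        acc2l = (i2 - r2l * v2l - k2l * x2l - kcl * (x2l - x1l)) / m2l
        acc1r = (f1 + i1r_ - r1r * v1r - k1r * x1r - kcr * (x1r - x2r)) / m1r
        acc2r = (i2r_ - r2r * v2r - k2r * x2r - kcr * (x2r - x1r)) / m2r

        x1l += dt_ms * v1l
        x2l += dt_ms * v2l
        x1r += dt_ms * v1r
        x2r += dt_ms * v2r
        v1l += dt_ms * acc1l
        v2l += dt_ms * acc2l
        v1r += dt_ms * acc1r
        v2r += dt_ms * acc2r

        if not (math.isfinite(x1l) and math.isfinite(x1r)
                and math.isfinite(x2l) and math.isfinite(x2r)):
            raise NumericDomainError(
                f"two-mass integration blew up at t = {i * dt:.4f} s"
            )
        out_1l[i] = x1l
        out_1r[i] = x1r
        if return_upper:
            out_2l[i] = x2l
            out_2r[i] = x2r

    fs = 1.0 / dt
    left = TimeSeries(out_1l, fs, label="x1 left")
    right = TimeSeries(out_1r, fs, label="x1 right")
    if return_upper:
        return (left, right,
                TimeSeries(out_2l, fs, label="x2 left"),
                TimeSeries(out_2r, fs, label="x2 right"))
    return left, right


def oscillation_envelope(ts: TimeSeries, window_s: float = 0.025) -> np.ndarray:
    """Rolling peak-to-peak amplitude, one value per sample.

    The window must span at least one oscillation cycle; peak-to-peak
    within a short window ignores the slow pressure-driven shift of the
    equilibrium position.
    """
    w = max(3, int(round(window_s * ts.fs)))
    return (maximum_filter1d(ts.samples, w, mode="nearest")
            - minimum_filter1d(ts.samples, w, mode="nearest"))


def onset_offset_pressures(left: TimeSeries, right: TimeSeries,
                           profile: PressureProfile,
                           amp_threshold: float = 0.05,
                           sustain_s: float = 0.05) -> tuple[float, float]:
    """Phonation threshold pressures (kPa) at oscillation onset and offset.

    The oscillation amplitude is the rolling peak-to-peak envelope of each
    lower mass (larger of the two folds); the threshold is
    ``amp_threshold`` times its maximum over the run.  "Sustained" means
    the envelope stays above threshold for at least ``sustain_s``.  Onset
    is the start of the first sustained run, offset the end of the last
    one; both are read off the pressure profile at those times.
    """
    env = np.maximum(oscillation_envelope(left), oscillation_envelope(right))
    peak = env.max()
    if peak <= 0.0:
        raise NoOnsetError("the folds never oscillate")
    above = env >= amp_threshold * peak
    need = max(1, int(round(sustain_s * left.fs)))

    runs = _true_runs(above)
    sustained = [(s, e) for s, e in runs if e - s >= need]
    if not sustained:
        raise NoOnsetError(
            "no oscillation sustained for the required duration"
        )
    onset_t = sustained[0][0] / left.fs
    offset_t = (sustained[-1][1] - 1) / left.fs
    return (float(profile.pressure_at(onset_t)),
            float(profile.pressure_at(offset_t)))


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of consecutive True values."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))
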