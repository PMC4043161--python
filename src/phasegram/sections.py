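"""Poincare sections through phase portraits and phasegram assembly.

A section is a line through the origin of the portrait plane at angle
``theta`` in [0, pi).  Each trajectory segment that crosses the line
contributes one intersection, located by linear interpolation and recorded
as a signed position along the line.  Per window, the positions are binned
into a histogram; histograms are normalized by the global maximum count and
stacked over time into the phasegram matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingConfig, embed, remove_dc, resolve_config, window_centers
from .types import (
    CrossingSet,
    InvalidParameterError,
    Phasegram,
    PhasegramError,
    PhasePortrait,
    TimeSeries,
    TrajectoryHistogram,
)

logger = logging.getLogger(__name__)


class DegenerateAttractorError(PhasegramError, RuntimeError):
    """No candidate section angle intersects the portraits."""


def _default_candidates() -> np.ndarray:
    return np.linspace(0.0, np.pi, 40, endpoint=False)


@dataclass(frozen=True)
class SectionConfig:
    """Where the Poincare section line lies.

    ``angle`` is in radians, in [0, pi); with ``auto_angle`` the angle is
    chosen from ``candidate_angles`` by maximizing the mean entropy of the
    crossing histogram over sampled portraits.
    """

    angle: float = 0.0
    auto_angle: bool = False
    candidate_angles: np.ndarray = field(default_factory=_default_candidates)

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle < np.pi:
            raise InvalidParameterError(
                f"angle must lie in [0, pi), got {self.angle}"
            )
        object.__setattr__(
            self, "candidate_angles",
            np.asarray(self.candidate_angles, dtype=np.float64),
        )


def poincare_crossings(portrait: PhasePortrait, angle: float) -> CrossingSet:
    """Intersections of the portrait trajectory with the section line.

    For consecutive points the perpendicular coordinate
    ``s = -u sin(angle) + v cos(angle)`` is tested for a sign change; the
    crossing position is the linearly interpolated coordinate along the
    line direction (cos, sin).  Points exactly on the line are attributed
    to the following segment, so a tangent touch is counted once.  Both
    crossing directions are kept (+1 towards positive s).
    """
    u, v = portrait.u, portrait.v
    sin_t, cos_t = math.sin(angle), math.cos(angle)
    s = -u * sin_t + v * cos_t
    p = u * cos_t + v * sin_t

    s0, s1 = s[:-1], s[1:]
    proper = s0 * s1 < 0.0
    on_line = (s0 == 0.0) & (s1 != 0.0)

    idx_p = np.flatnonzero(proper)
    frac = s0[idx_p] / (s0[idx_p] - s1[idx_p])
    pos_p = p[idx_p] + frac * (p[idx_p + 1] - p[idx_p])

    idx_z = np.flatnonzero(on_line)
    pos_z = p[idx_z]

    idx = np.concatenate([idx_p, idx_z])
    order = np.argsort(idx, kind="stable")
    positions = np.concatenate([pos_p, pos_z])[order]
    directions = np.where(s1[idx] > 0.0, 1, -1)[order]
    return CrossingSet(positions, directions, portrait.center_time_s)


def histogram_edges(bin_width: float, range_limit: float) -> np.ndarray:
    """Uniform bin edges symmetric about 0 with a bin centred at 0."""
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    k = max(1, int(math.ceil((range_limit - bin_width / 2) / bin_width)))
    return (np.arange(-(k + 0.5), k + 0.6) * bin_width)


def crossings_histogram(crossings: CrossingSet, bin_width: float,
                        range_limit: float = 1.0) -> TrajectoryHistogram:
    """Bin crossing positions on a grid symmetric about zero.

    If a crossing falls outside ``range_limit`` the grid is extended so no
    crossing is ever dropped (a notice is logged).
    """
    pos = crossings.positions
    limit = float(range_limit)
    if pos.size:
        needed = float(np.max(np.abs(pos)))
        if needed > limit:
            logger.info(
                "extending histogram range from %.4g to %.4g to keep all "
                "crossings", limit, needed,
            )
            limit = needed
    edges = histogram_edges(bin_width, limit)
    counts, _ = np.histogram(pos, bins=edges)
    return TrajectoryHistogram(edges, counts, crossings.center_time_s)


def histogram_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of a histogram's occupancy distribution."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def select_angle(portraits: list[PhasePortrait],
                 candidates: np.ndarray | None = None,
                 bin_width: float = 0.005) -> float:
    """Section angle maximizing mean crossing-histogram entropy.

    This is the package's automated stand-in for manually rotating the
    section until it reveals the attractor's full structure: an angle whose
    crossings spread over many bins carries more information than one whose
    crossings collapse onto few.  Ties resolve to the smallest angle.
    """
    if not portraits:
        raise InvalidParameterError("need at least one portrait")
    cands = _default_candidates() if candidates is None else \
        np.asarray(candidates, dtype=np.float64)
    if cands.size == 0:
        raise InvalidParameterError("need at least one candidate angle")

    best_angle = None
    best_score = -np.inf
    any_crossings = False
    for angle in np.sort(cands):
        scores = []
        for portrait in portraits:
            cs = poincare_crossings(portrait, float(angle))
            if len(cs):
                any_crossings = True
            hist = crossings_histogram(cs, bin_width)
            scores.append(histogram_entropy(hist.counts))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score = score
            best_angle = float(angle)
    if not any_crossings:
        raise DegenerateAttractorError(
            "no candidate angle intersects any portrait"
        )
    return best_angle


def revolution_crossings(ts: TimeSeries, center_i: int, delay_n: int,
                         angle: float, n_revolutions: int,
                         period_samples: float) -> CrossingSet:
    """Crossings of a delay portrait spanning whole limit-cycle revolutions.

    The window is aligned to start just before an ascending crossing of
    the section, then spans ``ceil((n_revolutions - 0.25) * period)``
    samples, which for any crossing phase contains exactly
    ``2 * n_revolutions`` intersections of a limit cycle whose period is
    ``period_samples``.
    """
    if n_revolutions < 1 or period_samples <= 0:
        raise InvalidParameterError("need >= 1 revolution and a period > 0")
    span = int(math.ceil((n_revolutions + 1) * period_samples))
    m = span  # generous search window around the centre
    from .embedding import EmbeddingConfig, delay_embed

    cfg = EmbeddingConfig(method="fixed-delay", delay_n=delay_n,
                          half_window_m=max(m, delay_n))
    portrait = delay_embed(ts, center_i, cfg)
    u, v = portrait.u, portrait.v
    s = -u * math.sin(angle) + v * math.cos(angle)
    asc = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
    if asc.size == 0:
        raise DegenerateAttractorError("no ascending section crossing found")
    start = int(asc[0])
    length = int(math.ceil((n_revolutions - 0.25) * period_samples))
    if start + length >= u.size:
        raise InvalidParameterError(
            "window too short for the requested revolutions"
        )
    sub = PhasePortrait(portrait.points[start: start + length + 1],
                        portrait.center_time_s, portrait.window_span)
    return poincare_crossings(sub, angle)


def colour_code(histograms: list[TrajectoryHistogram]) -> np.ndarray:
    """Flatten histograms to colour intensities in [0, 1].

    The normalizer ``hist_max`` is the global maximum bin count over all
    histograms, so strips are comparable across the whole phasegram.
    All-zero input maps to all-zero rows.
    """
    if not histograms:
        raise InvalidParameterError("need at least one histogram")
    hist_max = max(int(h.counts.max()) for h in histograms)
    denom = hist_max if hist_max > 0 else 1
    return np.vstack([h.counts / denom for h in histograms])


def build_phasegram(ts: TimeSeries,
                    ecfg: EmbeddingConfig | None = None,
                    scfg: SectionConfig | None = None,
                    bin_width: float = 0.005,
                    ts_y: TimeSeries | None = None,
                    dc_remove: bool = True) -> Phasegram:
    """Full pipeline: windows -> portraits -> sections -> strips -> matrix.

    With ``ts_y`` the portrait plane is the two-channel plane
    (ts[j], ts_y[j]) instead of a delay embedding - the natural choice when
    two synchronized observables (e.g. left and right vocal-fold
    displacement) are available.
    """
    ecfg = ecfg or EmbeddingConfig()
    scfg = scfg or SectionConfig()

    if dc_remove:
        ts = remove_dc(ts)
        if ts_y is not None:
            ts_y = remove_dc(ts_y)

    if ts_y is not None:
        if len(ts_y) != len(ts) or ts_y.fs != ts.fs:
            raise InvalidParameterError(
                "two-channel portraits need equally sampled channels"
            )
        m = ecfg.half_window_m
        if m is None:
            m = max(1, int(round(ecfg.window_s * ts.fs)) // 2)
        from dataclasses import replace
        ecfg = replace(ecfg, method="hilbert", half_window_m=m)  # n = 0 windowing
        centers = window_centers(ts, ecfg)
        portraits = [
            PhasePortrait(
                np.column_stack([ts.samples[c - m: c + m + 1],
                                 ts_y.samples[c - m: c + m + 1]]),
                c / ts.fs, (c - m, c + m))
            for c in centers
        ]
    else:
        ecfg = resolve_config(ts, ecfg)
        centers = window_centers(ts, ecfg)
        portraits = [embed(ts, int(c), ecfg) for c in centers]

    if scfg.auto_angle:
        stride = max(1, len(portraits) // 10)
        angle = select_angle(portraits[::stride], scfg.candidate_angles,
                             bin_width)
    else:
        angle = scfg.angle

    crossing_sets = [poincare_crossings(p, angle) for p in portraits]
    limit = max((float(np.max(np.abs(cs.positions))) for cs in crossing_sets
                 if len(cs)), default=1.0)
    edges = histogram_edges(bin_width, limit)
    histograms = [
        TrajectoryHistogram(edges, np.histogram(cs.positions, bins=edges)[0],
                            cs.center_time_s)
        for cs in crossing_sets
    ]
    matrix = colour_code(histograms)
    hist_max = max(int(h.counts.max()) for h in histograms)
    centers_arr = np.asarray(centers)
    meta = {
        "fs": ts.fs,
        "label": ts.label,
        "angle_rad": float(angle),
        "auto_angle": bool(scfg.auto_angle),
        "bin_width": float(bin_width),
        "hist_max": hist_max,
        "delay_n": ecfg.delay_n if ts_y is None else 0,
        "half_window_m": ecfg.half_window_m,
        "hop_s": ecfg.hop_s,
        "method": ecfg.method if ts_y is None else "two-channel",
        "dc_removed": bool(dc_remove),
    }
    logger.info(
        "phasegram: %d strips, %d bins, angle %.4f rad, delay %s, hist_max %d",
        len(histograms), edges.size - 1, angle, meta["delay_n"], hist_max,
    )
    return Phasegram(matrix, centers_arr / ts.fs,
                     0.5 * (edges[:-1] + edges[1:]), meta)
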