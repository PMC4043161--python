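"""Reading dynamics off a phasegram.

The number and stability of horizontal lines in a phasegram encode the
oscillatory regime: one line (or none) means no oscillation, 2n locally
stable lines a limit cycle with n-fold subharmonic structure (2 lines =
simple periodic, 4 = period doubling, 6 = period tripling, ...), and
multiple unstable lines irregular dynamics (chaos, quasi-periodicity or
drifting parameters).  This module turns a phasegram into labelled regime
segments, bifurcation events, and - when a control-parameter trace is
available - a bifurcation diagram with sweep-direction splitting that makes
hysteresis visible.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .types import (
    BifurcationDiagram,
    InvalidParameterError,
    Phasegram,
    RegimeSegment,
    TimeSeries,
)

logger = logging.getLogger(__name__)

LABEL_STATIC = "static"
LABEL_PERIODIC = "periodic"
LABEL_IRREGULAR = "irregular"


def subharmonic_label(p: int) -> str:
    return f"subharmonic({p})"


def detect_lines(pg: Phasegram, intensity_eps: float = 0.05
                 ) -> list[np.ndarray]:
    """Per-column line positions (amplitude units).

    A line is a contiguous run of bins with intensity >= ``intensity_eps``,
    located at its intensity-weighted centroid.
    """
    if not 0.0 <= intensity_eps <= 1.0:
        raise InvalidParameterError("intensity_eps must lie in [0, 1]")
    out: list[np.ndarray] = []
    centers = pg.bin_centers
    for row in pg.matrix:
        mask = row >= intensity_eps if intensity_eps > 0 else row > 0
        positions = []
        j = 0
        n = mask.size
        while j < n:
            if mask[j]:
                k = j
                while k < n and mask[k]:
                    k += 1
                w = row[j:k]
                positions.append(float(np.sum(w * centers[j:k]) / np.sum(w)))
                j = k
            else:
                j += 1
        out.append(np.asarray(positions))
    return out


def _column_label(count: int) -> str:
    if count <= 1:
        return LABEL_STATIC
    if count == 2:
        return LABEL_PERIODIC
    if count % 2 == 0:
        return subharmonic_label(count // 2)
    return LABEL_IRREGULAR


def _local_stability(lines: list[np.ndarray], cols: range,
                     bin_width: float) -> float:
    """Fraction of adjacent column pairs whose lines persist.

    A pair is stable when both columns show the same line count and each
    line moves by at most one bin width between them.  This tracks the
    "locally stable lines" reading: slowly drifting lines (a swept system
    parameter) count as stable, column-to-column jumps do not.
    """
    pairs = 0
    ok = 0
    for i in cols:
        if i + 1 not in cols:
            continue
        pairs += 1
        a, b = lines[i], lines[i + 1]
        if a.size == b.size and a.size > 0 and \
                np.all(np.abs(np.sort(a) - np.sort(b)) <= bin_width):
            ok += 1
    return ok / pairs if pairs else 1.0


def _segment_stability(lines: list[np.ndarray], cols: range,
                       bin_width: float) -> float:
    """Fraction of columns whose line positions stay within one bin of the
    segment's median line positions (compared per sorted rank)."""
    counts = [lines[i].size for i in cols]
    if not counts:
        return 0.0
    common = Counter(counts).most_common(1)[0][0]
    if common == 0:
        return 1.0
    stacked = [np.sort(lines[i]) for i in cols if lines[i].size == common]
    if not stacked:
        return 0.0
    medians = np.median(np.vstack(stacked), axis=0)
    ok = 0
    for i in cols:
        if lines[i].size == common and \
                np.all(np.abs(np.sort(lines[i]) - medians) <= bin_width):
            ok += 1
    return ok / len(counts)


def classify_regimes(pg: Phasegram, min_duration_s: float = 0.1,
                     intensity_eps: float = 0.05,
                     stability_threshold: float = 0.8
                     ) -> list[RegimeSegment]:
    """Segment the phasegram into labelled oscillatory regimes.

    Columns are labelled by their stable-line count (0-1 static, 2
    periodic, 2n subharmonic(n), odd counts irregular); adjacent columns
    with equal labels merge into segments; periodic/subharmonic segments
    whose lines wander (stability below ``stability_threshold``) are
    relabelled irregular; segments shorter than ``min_duration_s`` are
    absorbed into their longer neighbour.
    """
    lines = detect_lines(pg, intensity_eps)
    times = pg.times_s
    n = len(lines)
    if n == 0:
        return []
    hop = float(times[1] - times[0]) if n > 1 else min_duration_s
    bw = pg.bin_width if np.isfinite(pg.bin_width) else 0.0

    labels = [_column_label(l.size) for l in lines]

    # merge -> [start, end) column ranges
    def merge(labels_per_col: list[str]) -> list[tuple[int, int, str]]:
        segs = []
        i = 0
        while i < n:
            j = i
            while j < n and labels_per_col[j] == labels_per_col[i]:
                j += 1
            segs.append((i, j, labels_per_col[i]))
            i = j
        return segs

    segs = merge(labels)

    # demote unstable line patterns to irregular, then re-merge
    relabelled = list(labels)
    for i0, i1, lab in segs:
        if lab in (LABEL_PERIODIC,) or lab.startswith("subharmonic"):
            stab = _local_stability(lines, range(i0, i1), bw)
            if stab < stability_threshold:
                for i in range(i0, i1):
                    relabelled[i] = LABEL_IRREGULAR
    segs = merge(relabelled)

    # absorb too-short segments into the longer neighbour
    min_cols = max(1, int(round(min_duration_s / hop)))
    segs = [list(s) for s in segs]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        sizes = [s[1] - s[0] for s in segs]
        order = int(np.argmin(sizes))
        if sizes[order] < min_cols:
            left = segs[order - 1] if order > 0 else None
            right = segs[order + 1] if order < len(segs) - 1 else None
            if right is None or (left is not None and
                                 (left[1] - left[0]) >= (right[1] - right[0])):
                left[1] = segs[order][1]
            else:
                right[0] = segs[order][0]
            del segs[order]
            # re-merge equal neighbours
            k = 0
            while k < len(segs) - 1:
                if segs[k][2] == segs[k + 1][2]:
                    segs[k][1] = segs[k + 1][1]
                    del segs[k + 1]
                else:
                    k += 1
            changed = True

    out = []
    for i0, i1, lab in segs:
        seg_lines = [lines[i] for i in range(i0, i1)]
        count = Counter(l.size for l in seg_lines).most_common(1)[0][0]
        stab = _segment_stability(lines, range(i0, i1), bw)
        t0 = times[i0] - hop / 2
        t1 = times[i1 - 1] + hop / 2
        out.append(RegimeSegment(float(t0), float(t1), lab, int(count),
                                 float(stab)))
    return out


def column_labels(pg: Phasegram, **kwargs) -> list[str]:
    """Per-column regime label (the segment label covering each column)."""
    segments = classify_regimes(pg, **kwargs)
    out = []
    for t in pg.times_s:
        lab = None
        for seg in segments:
            if seg.t_start <= t <= seg.t_end:
                lab = seg.label
                break
        out.append(lab if lab is not None else LABEL_STATIC)
    return out


def detect_bifurcations(segments: list[RegimeSegment]
                        ) -> list[tuple[float, str, str]]:
    """Regime-change events: (time, from-label, to-label) per boundary."""
    events = []
    for a, b in zip(segments, segments[1:]):
        if abs(a.t_end - b.t_start) > 1e-9:
            raise InvalidParameterError("segments must be contiguous")
        events.append((a.t_end, a.label, b.label))
    return events


def bifurcation_diagram(pg: Phasegram, control: TimeSeries,
                        intensity_eps: float = 0.05,
                        control_name: str = "control",
                        **classify_kwargs) -> BifurcationDiagram:
    """Line positions against the control parameter, split by sweep phase.

    The control series is linearly interpolated to the column centre
    times; columns up to the control's global maximum belong to the rising
    branch, the rest to the falling branch.  A control trace with interior
    local extrema beyond the global maximum is tolerated with a notice
    (points are still split at the global maximum).
    """
    ctrl = np.interp(pg.times_s, control.times, control.samples)
    if ctrl.size < 1:
        raise InvalidParameterError("control does not cover the phasegram")
    lines = detect_lines(pg, intensity_eps)
    labels = column_labels(pg, intensity_eps=intensity_eps, **classify_kwargs)
    imax = int(np.argmax(ctrl))
    d = np.diff(ctrl)
    n_extrema = int(np.sum(np.diff(np.sign(d[d != 0])) != 0)) if d.size else 0
    if n_extrema > 1:
        logger.info("control trace has %d interior extrema; splitting at the "
                    "global maximum only", n_extrema)

    def collect(cols):
        c_out, p_out, l_out = [], [], []
        for i in cols:
            for pos in lines[i]:
                c_out.append(ctrl[i])
                p_out.append(pos)
                l_out.append(labels[i])
        return (np.asarray(c_out), np.asarray(p_out),
                np.asarray(l_out, dtype=object))

    cr, pr, lr = collect(range(0, imax + 1))
    cf, pf, lf = collect(range(imax + 1, len(ctrl)))
    return BifurcationDiagram(cr, pr, cf, pf, lr, lf, control_name)


def hysteresis_intervals(diagram: BifurcationDiagram,
                         n_bins: int = 50) -> list[tuple[float, float]]:
    """Control intervals where rising and falling regimes differ.

    The control axis is discretized into ``n_bins`` equal bins; a bin is
    hysteretic when both branches visit it with different dominant regime
    labels.  Adjacent hysteretic bins merge into intervals.
    """
    all_ctrl = np.concatenate([diagram.control_rising, diagram.control_falling])
    if all_ctrl.size == 0:
        return []
    lo, hi = float(all_ctrl.min()), float(all_ctrl.max())
    if hi <= lo:
        return []
    edges = np.linspace(lo, hi, n_bins + 1)

    def dominant(ctrl, labels):
        out = {}
        idx = np.clip(np.digitize(ctrl, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = labels[idx == b]
            if sel.size:
                out[b] = Counter(sel.tolist()).most_common(1)[0][0]
        return out

    rise = dominant(diagram.control_rising, diagram.labels_rising)
    fall = dominant(diagram.control_falling, diagram.labels_falling)
    flagged = [b for b in range(n_bins)
               if b in rise and b in fall and rise[b] != fall[b]]
    intervals = []
    for b in flagged:
        span = (float(edges[b]), float(edges[b + 1]))
        if intervals and abs(intervals[-1][1] - span[0]) < 1e-12:
            intervals[-1] = (intervals[-1][0], span[1])
        else:
            intervals.append(span)
    return intervals
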