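"""File formats and rendering.

WAV (PCM 16/24/32 or float-32) and single-column delimited text are the
exchange formats for signals; phasegram matrices export as delimited text
with axis headers and render as PNG.  Every export can carry a flat
key=value sidecar with the resolved configuration so figures are
regenerable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.io import wavfile

from .embedding import EmbeddingConfig, embed, remove_dc, resolve_config, window_centers
from .types import InvalidParameterError, Phasegram, PhasegramError, TimeSeries

logger = logging.getLogger(__name__)


class FileFormatError(PhasegramError, ValueError):
    """The file cannot be read as a supported signal format."""


_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}


def read_timeseries(path: str | Path, fs_override: float | None = None,
                    channel: int = 0) -> TimeSeries:
    """Read a signal from WAV or delimited text.

    Text files hold one amplitude per line; the sampling rate comes from a
    ``# fs=<Hz>`` header line or ``fs_override`` (the override wins).  For
    multi-channel WAV the ``channel`` index selects one channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FileFormatError(f"{path} is empty")
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(path)
        if data.dtype.kind == "i":
            data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
        elif data.dtype.kind == "u":   # 8-bit unsigned PCM
            data = (data.astype(np.float64) - 128.0) / 128.0
        else:
            data = data.astype(np.float64)
        if data.ndim == 2:
            if not 0 <= channel < data.shape[1]:
                raise FileFormatError(
                    f"channel {channel} out of range for {data.shape[1]}-channel file"
                )
            data = data[:, channel]
        return TimeSeries(data, float(fs_override or fs), label=path.stem)
    if path.suffix.lower() in _TEXT_SUFFIXES or path.suffix == "":
        fs = fs_override
        values = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.lower().startswith("fs") and "=" in body:
                        header_fs = float(body.split("=", 1)[1])
                        if fs_override is None:
                            fs = header_fs
                    continue
                values.append(float(line.split(",")[channel]
                                    if "," in line else line.split()[channel]))
        if fs is None:
            raise FileFormatError(
                f"{path}: sampling rate missing (no '# fs=' header; pass fs)"
            )
        return TimeSeries(np.asarray(values), float(fs), label=path.stem)
    raise FileFormatError(f"unsupported file type: {path.suffix!r}")


def write_timeseries(ts: TimeSeries, path: str | Path,
                     encoding: str = "float32",
                     extra: TimeSeries | None = None) -> Path:
    """Write a signal as WAV (float-32 default, or pcm16) or text.

    ``extra`` adds a second channel (WAV stereo / second text column),
    used for the two-channel vocal-fold output.
    """
    path = Path(path)
    data = ts.samples
    if extra is not None:
        if len(extra) != len(ts):
            raise InvalidParameterError("channels must have equal length")
        data = np.column_stack([ts.samples, extra.samples])
    if path.suffix.lower() == ".wav":
        if encoding == "float32":
            wavfile.write(path, int(round(ts.fs)), data.astype(np.float32))
        elif encoding == "pcm16":
            peak = np.abs(data).max()
            scaled = data / peak if peak > 1.0 else data
            wavfile.write(path, int(round(ts.fs)),
                          (scaled * 32767).astype(np.int16))
        else:
            raise InvalidParameterError(f"unknown encoding {encoding!r}")
    else:
        header = f"# fs={ts.fs:g}\n# label={ts.label}\n"
        with open(path, "w") as fh:
            fh.write(header)
            if data.ndim == 1:
                fh.writelines(f"{v:.9g}\n" for v in data)
            else:
                fh.writelines(
                    ",".join(f"{v:.9g}" for v in row) + "\n" for row in data
                )
    return path


def save_config(cfg: dict[str, Any], path: str | Path) -> Path:
    """Flat key=value sidecar (one pair per line)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(cfg):
            fh.write(f"{key}={cfg[key]}\n")
    return path


def load_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def export_phasegram_text(pg: Phasegram, path: str | Path) -> Path:
    """Matrix as delimited text: rows = bins, columns = time instants.

    Header lines carry the time axis, the bin-centre axis and the full
    provenance metadata.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(pg.meta):
            fh.write(f"# {key}={pg.meta[key]}\n")
        fh.write("# times_s=" + ",".join(f"{t:.9g}" for t in pg.times_s) + "\n")
        fh.write("# bin_centers=" +
                 ",".join(f"{b:.9g}" for b in pg.bin_centers) + "\n")
        for row in pg.matrix.T:      # one output row per histogram bin
            fh.write(",".join(f"{v:.6g}" for v in row) + "\n")
    return path


def render_phasegram(pg: Phasegram, path: str | Path,
                     events: list[tuple[float, str, str]] | None = None,
                     dpi: int = 100) -> Path:
    """Render to PNG: time on x (s), bin position on y, darkness = intensity.

    At least one pixel per (column, bin) and no smoothing, so line counts
    stay readable off the image.
    """
    path = Path(path)
    n_cols, n_bins = pg.n_windows, pg.n_bins
    width_in = max(6.0, n_cols / dpi * 1.1 + 1.0)
    height_in = max(4.0, n_bins / dpi * 1.1 + 1.0)
    fig, ax = plt.subplots(figsize=(width_in, height_in), dpi=dpi)
    t0, t1 = float(pg.times_s[0]), float(pg.times_s[-1])
    if t1 <= t0:           # single-strip phasegram still needs a finite span
        t1 = t0 + 1.0
    half_bw = pg.bin_width / 2 if np.isfinite(pg.bin_width) else 0.5
    extent = (t0, t1, float(pg.bin_centers[0] - half_bw),
              float(pg.bin_centers[-1] + half_bw))
    ax.imshow(pg.matrix.T, origin="lower", aspect="auto", cmap="gray_r",
              vmin=0.0, vmax=1.0, extent=extent, interpolation="nearest")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Poincare-section position (amplitude units)")
    if events:
        for t, _, _ in events:
            ax.axvline(t, color="tab:red", lw=0.8, ls="--")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def export_portrait_frames(ts: TimeSeries, cfg: EmbeddingConfig,
                           out_dir: str | Path,
                           frame_interval_s: float = 0.04,
                           audio_name: str = "audio.wav") -> list[Path]:
    """Numbered phase-portrait frames plus the signal as a WAV audio track.

    Frames are extracted every ``frame_interval_s`` (0.04 s = 25 fps); at
    least one frame is always emitted.  Video muxing is left to an
    external tool (e.g. ffmpeg over the numbered PNGs plus the WAV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditioned = remove_dc(ts)
    rcfg = resolve_config(conditioned, cfg)
    centers = window_centers(conditioned, rcfg)
    # one frame per interval from t = 0; instants snap to the nearest
    # realizable window centre (duplicates at the edges are kept so the
    # frame train stays at a constant rate)
    n_frames = max(1, int(np.ceil(len(ts) / ts.fs / frame_interval_s - 1e-9)))
    wanted = np.arange(n_frames) * frame_interval_s * ts.fs
    picked = centers[np.minimum(
        np.searchsorted(centers, wanted), centers.size - 1)]
    span = float(np.abs(conditioned.samples).max()) * 1.05 or 1.0
    paths = []
    for k, c in enumerate(picked):
        portrait = embed(conditioned, int(c), rcfg)
        fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
        ax.plot(portrait.u, portrait.v, lw=0.6, color="k")
        ax.set_xlim(-span, span)
        ax.set_ylim(-span, span)
        ax.set_xlabel("x(t)")
        ax.set_ylabel("x(t + delay)" if rcfg.method != "hilbert"
                      else "Im analytic")
        ax.set_title(f"t = {c / ts.fs:.3f} s")
        frame_path = out_dir / f"frame_{k:05d}.png"
        fig.tight_layout()
        fig.savefig(frame_path)
        plt.close(fig)
        paths.append(frame_path)
    write_timeseries(ts, out_dir / audio_name)
    paths.append(out_dir / audio_name)
    return paths
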