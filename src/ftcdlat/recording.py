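"""Recording data model, the ``.ftcd.tsv`` text dialect, and rate conversion.

A recording holds two synchronized cerebral blood-flow-velocity envelope
channels (left / right middle cerebral artery) plus trial-start markers.

File dialect (``.ftcd.tsv``):

* line 1 — header: ``#fs=<Hz> subject=<id>``
* line 2 — column header: ``time_s<TAB>left<TAB>right<TAB>marker``
* data lines — tab-separated; ``marker`` is 0 or 1 (1 = trial start at
  that sample).  The marker column may be absent ("no markers").

UTF-8, LF line endings.  Velocity samples are written with 17 significant
digits so a write/read round trip is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import signal as _sig

__all__ = [
    "Recording",
    "TrialAnnotations",
    "RecordingParseError",
    "read_recording",
    "write_recording",
    "downsample",
]

TRIAL_START = "trial_start"

#: anti-alias cutoff as a fraction of the target rate
_AA_CUTOFF_FRAC = 0.4
#: Butterworth order of the zero-phase anti-alias filter
_AA_ORDER = 4


class RecordingParseError(ValueError):
    """Malformed ``.ftcd.tsv`` content; the message names the line number."""


@dataclass
class Recording:
    """Two-channel velocity recording with trial-start markers.

    Parameters
    ----------
    subject_id : str
        Identifier copied into result rows.
    fs : float
        Sampling rate in Hz, strictly positive and finite.
    left, right : ndarray
        Velocity series of identical length ``N >= 1``; all finite.
    markers : list of (int, str)
        ``(sample_index, label)`` events, strictly increasing indices in
        ``[0, N)``; label is :data:`TRIAL_START`.
    t0 : float
        Time of the first sample in seconds.
    meta : dict
        Free-form annotations.
    """

    subject_id: str
    fs: float
    left: np.ndarray
    right: np.ndarray
    markers: list[tuple[int, str]] = field(default_factory=list)
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.ndim != 1 or self.right.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if self.left.size != self.right.size:
            raise ValueError("left and right channels differ in length")
        if self.left.size < 1:
            raise ValueError("recording must contain at least one sample")
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        if not (np.isfinite(self.left).all() and np.isfinite(self.right).all()):
            raise ValueError("velocity samples must be finite")
        n = self.left.size
        prev = -1
        for idx, label in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker out of range: index {idx} not in [0, {n})")
            if idx <= prev:
                raise ValueError("marker indices must be strictly increasing")
            prev = idx

    @property
    def n_samples(self) -> int:
        return int(self.left.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def marker_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.markers], dtype=int)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class TrialAnnotations:
    """Per-trial validity annotations (1-based trial indices).

    Trials are excluded when the child spoke during baseline or was silent
    during the activation period; every excluded index carries a reason.
    """

    excluded_trials: set[int] = field(default_factory=set)
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i in self.excluded_trials:
            if i < 1:
                raise ValueError("trial indices are 1-based and positive")
            if i not in self.reasons:
                raise ValueError(f"excluded trial {i} has no reason")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str]]) -> "TrialAnnotations":
        pairs = list(pairs)
        return cls(
            excluded_trials={i for i, _ in pairs},
            reasons={i: r for i, r in pairs},
        )


def read_recording(path: str | Path, dialect: str = "ftcd.tsv") -> Recording:
    """Read a recording from the documented text dialect.

    Raises :class:`RecordingParseError` (naming the offending line) on a
    malformed header, a non-numeric sample, or a non-monotone time column.
    """
    if dialect != "ftcd.tsv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise RecordingParseError("line 1: missing '#fs=... subject=...' header")
    header = {}
    for tok in lines[0][1:].split():
        if "=" not in tok:
            raise RecordingParseError(f"line 1: malformed header token {tok!r}")
        k, v = tok.split("=", 1)
        header[k] = v
    if "fs" not in header:
        raise RecordingParseError("line 1: header missing fs")
    try:
        fs = float(header["fs"])
    except ValueError:
        raise RecordingParseError(f"line 1: non-numeric fs {header['fs']!r}") from None
    subject = header.get("subject", "")

    if len(lines) < 2:
        raise RecordingParseError("line 2: missing column header")
    cols = lines[1].split("\t")
    if cols[:3] != ["time_s", "left", "right"]:
        raise RecordingParseError(
            "line 2: column header must start with 'time_s\\tleft\\tright'"
        )
    has_marker = len(cols) > 3 and cols[3] == "marker"

    times: list[float] = []
    left: list[float] = []
    right: list[float] = []
    marker_rows: list[int] = []
    for ln, raw in enumerate(lines[2:], start=3):
        if not raw:
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise RecordingParseError(f"line {ln}: expected >= 3 columns")
        try:
            t = float(parts[0])
            lv = float(parts[1])
            rv = float(parts[2])
        except ValueError:
            raise RecordingParseError(f"line {ln}: non-numeric sample") from None
        if times and t <= times[-1]:
            raise RecordingParseError(f"line {ln}: non-monotone time column")
        times.append(t)
        left.append(lv)
        right.append(rv)
        if has_marker and len(parts) > 3 and parts[3].strip() not in ("", "0"):
            if parts[3].strip() != "1":
                raise RecordingParseError(f"line {ln}: marker must be 0 or 1")
            marker_rows.append(len(times) - 1)
    if not times:
        raise RecordingParseError("line 3: no samples")
    t0 = times[0]
    markers = [(i, TRIAL_START) for i in marker_rows]
    try:
        return Recording(
            subject_id=subject, fs=fs, left=np.array(left), right=np.array(right),
            markers=markers, t0=t0,
        )
    except ValueError as exc:
        raise RecordingParseError(str(exc)) from None


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` in the ``.ftcd.tsv`` dialect (round-trip safe)."""
    path = Path(path)
    marker_set = {i for i, _ in rec.markers}
    out = [f"#fs={rec.fs:.17g} subject={rec.subject_id}"]
    out.append("time_s\tleft\tright\tmarker")
    t = rec.times()
    for i in range(rec.n_samples):
        m = 1 if i in marker_set else 0
        out.append(f"{t[i]:.17g}\t{rec.left[i]:.17g}\t{rec.right[i]:.17g}\t{m}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")


def _remap_index(idx: int, ratio: float, n_out: int) -> int:
    # nearest output sample; exact halves round DOWN
    j = int(math.ceil(idx * ratio - 0.5))
    return min(max(j, 0), n_out - 1)


def antialias_filter(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass at ``0.4 * target_fs`` (the
    documented anti-alias stage; exposed so tests can apply it verbatim)."""
    wn = _AA_CUTOFF_FRAC * target_fs / (fs / 2.0)
    if wn >= 1.0:
        return np.asarray(x, dtype=float).copy()
    sos = _sig.butter(_AA_ORDER, wn, btype="low", output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(x, dtype=float))


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias low-pass then reduce ``rec`` to ``target_fs``.

    Integer rate ratios take a decimation path; otherwise the filtered
    signal is linearly interpolated onto the target grid.  Marker indices
    are remapped to the nearest output sample (ties round down).
    """
    if not (target_fs > 0):
        raise ValueError("target_fs must be > 0")
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording rate {rec.fs}")
    if target_fs == rec.fs:
        return replace(rec, left=rec.left.copy(), right=rec.right.copy(),
                       markers=list(rec.markers))

    lf = antialias_filter(rec.left, rec.fs, target_fs)
    rf = antialias_filter(rec.right, rec.fs, target_fs)
    ratio = target_fs / rec.fs
    q = rec.fs / target_fs
    if abs(q - round(q)) < 1e-9:
        q = int(round(q))
        left = lf[::q].copy()
        right = rf[::q].copy()
        n_out = left.size
    else:
        n_out = int(math.floor(rec.n_samples * ratio))
        t_in = np.arange(rec.n_samples) / rec.fs
        t_out = np.arange(n_out) / target_fs
        left = np.interp(t_out, t_in, lf)
        right = np.interp(t_out, t_in, rf)

    markers = []
    prev = -1
    for idx, label in rec.markers:
        j = _remap_index(idx, ratio, n_out)
        if j <= prev:  # two markers collapsed onto one output sample
            raise ValueError("markers collide after downsampling")
        markers.append((j, label))
        prev = j
    return Recording(
        subject_id=rec.subject_id, fs=float(target_fs), left=left, right=right,
        markers=markers, t0=rec.t0, meta=dict(rec.meta),
    )
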