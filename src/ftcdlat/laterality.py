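"""Laterality index computation and left / bilateral / right classification.

The laterality index (LI) is the mean left-minus-right velocity difference
in a 2 s window centred on the peak of the grand-average difference curve
within the period of interest (4-14 s after the cue to speak).  Positive
LI means greater left-hemisphere activation.  The LI is computed per
epoch, giving a standard error and a 95% confidence interval; a CI that
spans zero yields the 'bilateral' category, and fewer accepted trials than
the minimum yields 'insufficient'.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

from .epochs import Epoch, EpochSpec

__all__ = [
    "LateralityResult",
    "average_difference",
    "find_peak",
    "window_mask",
    "compute_li",
    "classify",
    "split_half",
    "result_to_row",
    "result_to_json",
]

CAT_LEFT = "left"
CAT_RIGHT = "right"
CAT_BILATERAL = "bilateral"
CAT_INSUFFICIENT = "insufficient"


@dataclass
class LateralityResult:
    subject_id: str
    li: float
    per_epoch_li: np.ndarray
    se: float
    ci95: tuple[float, float]
    peak_latency_s: float
    n_accepted: int
    category: str
    li_odd: float
    li_even: float
    diff_t: np.ndarray = field(repr=False, default=None)  # type: ignore
    diff_curve: np.ndarray = field(repr=False, default=None)  # type: ignore


def average_difference(epochs: Sequence[Epoch]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean left-minus-right curve over accepted epochs.

    Returns ``(t, diff)`` on the common cue-relative time axis.
    """
    acc = [e for e in epochs if e.is_accepted]
    if not acc:
        raise ValueError("no accepted epochs to average")
    t = acc[0].t
    for e in acc[1:]:
        if len(e.t) != len(t) or not np.allclose(e.t, t):
            raise ValueError("epochs do not share a common time axis")
    diff = np.mean([e.diff for e in acc], axis=0)
    return t, diff


def find_peak(t: np.ndarray, diff: np.ndarray, spec: EpochSpec) -> float:
    """Latency (s after cue onset) of the peak difference within the POI.

    ``spec.peak_mode='abs'`` (default) takes the maximum of ``|diff|`` with
    the curve's sign retained downstream; ``'signed'`` takes the maximum of
    the signed curve.  Ties break to the earliest latency.
    """
    p0, p1 = spec.poi_s
    mask = (t >= p0 - 1e-12) & (t <= p1 + 1e-12)
    if not mask.any():
        raise ValueError("period of interest contains no samples")
    seg = diff[mask]
    if np.isnan(seg).all():
        raise ValueError("period of interest is all-NaN")
    score = np.abs(seg) if spec.peak_mode == "abs" else seg
    idx = int(np.nanargmax(score))  # argmax returns the first maximum
    return float(t[mask][idx])


def window_mask(t: np.ndarray, peak_latency_s: float, spec: EpochSpec) -> np.ndarray:
    """Samples of the LI window centred on the peak, clipped to the epoch."""
    half = spec.li_window_s / 2.0
    lo = max(peak_latency_s - half, t[0])
    hi = min(peak_latency_s + half, t[-1])
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if not mask.any():
        raise ValueError("laterality window contains no samples")
    return mask


def _window_means(epochs: Sequence[Epoch], peak_latency_s: float,
                  spec: EpochSpec) -> np.ndarray:
    mask = window_mask(epochs[0].t, peak_latency_s, spec)
    return np.array([e.diff[mask].mean() for e in epochs])


def split_half(epochs: Sequence[Epoch], peak_latency_s: float,
               spec: EpochSpec) -> tuple[float, float]:
    """Mean LI of odd- and even-positioned accepted epochs at the shared
    peak latency.  Parity follows position in the accepted sequence
    (1st, 3rd, ... are odd), so halves stay balanced after rejections.
    """
    acc = [e for e in epochs if e.is_accepted]
    odd = acc[0::2]
    even = acc[1::2]
    if not odd or not even:
        raise ValueError("split half is empty")
    li_odd = float(_window_means(odd, peak_latency_s, spec).mean())
    li_even = float(_window_means(even, peak_latency_s, spec).mean())
    return li_odd, li_even


def classify(li: float, ci95: tuple[float, float], n_accepted: int,
             spec: EpochSpec) -> str:
    """Category from the accepted-trial count and the CI position."""
    if n_accepted < spec.min_trials:
        return CAT_INSUFFICIENT
    lo, hi = ci95
    if lo > 0:
        return CAT_LEFT
    if hi < 0:
        return CAT_RIGHT
    return CAT_BILATERAL


def compute_li(epochs: Sequence[Epoch], spec: EpochSpec | None = None,
               subject_id: str = "") -> LateralityResult:
    """Full laterality result from a session's (possibly mixed-status)
    epoch list.

    The peak is located on the grand-average difference curve; every
    accepted epoch's LI is the mean of its own difference over the shared
    2 s window.  With zero accepted epochs the result is 'insufficient'
    with NaN statistics.
    """
    spec = spec or EpochSpec()
    acc = [e for e in epochs if e.is_accepted]
    n = len(acc)
    if n == 0:
        return LateralityResult(
            subject_id=subject_id, li=float("nan"), per_epoch_li=np.array([]),
            se=float("nan"), ci95=(float("nan"), float("nan")),
            peak_latency_s=float("nan"), n_accepted=0,
            category=CAT_INSUFFICIENT, li_odd=float("nan"),
            li_even=float("nan"), diff_t=None, diff_curve=None,
        )
    t, diff = average_difference(acc)
    peak = find_peak(t, diff, spec)
    per_epoch = _window_means(acc, peak, spec)
    li = float(per_epoch.mean())
    if n >= 2:
        se = float(per_epoch.std(ddof=1) / np.sqrt(n))
        if se == 0.0:
            warnings.warn("degenerate CI: identical per-epoch LIs", stacklevel=2)
            ci = (li, li)
        else:
            crit = (_st.t.ppf(0.975, n - 1) if spec.ci_method == "t"
                    else _st.norm.ppf(0.975))
            ci = (li - crit * se, li + crit * se)
    else:
        se = float("nan")
        ci = (float("nan"), float("nan"))
    try:
        li_odd, li_even = split_half(acc, peak, spec)
    except ValueError:
        li_odd = li_even = float("nan")
    return LateralityResult(
        subject_id=subject_id, li=li, per_epoch_li=per_epoch, se=se, ci95=ci,
        peak_latency_s=peak, n_accepted=n,
        category=classify(li, ci, n, spec), li_odd=li_odd, li_even=li_even,
        diff_t=t, diff_curve=diff,
    )


def result_to_row(r: LateralityResult) -> dict:
    """One-row summary suitable for a per-subject CSV."""
    return {
        "subject_id": r.subject_id,
        "n_accepted": r.n_accepted,
        "li": r.li,
        "se": r.se,
        "ci_low": r.ci95[0],
        "ci_high": r.ci95[1],
        "peak_latency_s": r.peak_latency_s,
        "category": r.category,
        "li_odd": r.li_odd,
        "li_even": r.li_even,
    }


def result_to_json(r: LateralityResult) -> str:
    full = dict(result_to_row(r))
    full["per_epoch_li"] = [float(x) for x in r.per_epoch_li]
    if r.diff_curve is not None:
        full["diff_t"] = [float(x) for x in r.diff_t]
        full["diff_curve"] = [float(x) for x in r.diff_curve]
    return json.dumps(full, indent=2, allow_nan=True)
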