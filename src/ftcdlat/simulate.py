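"""Synthetic Doppler-session and cohort generator with known ground truth.

A session is ``n_trials`` repeats of a 30 s trial: 12 s silent watching
(baseline), a cue to speak, 10 s talking, 8 s rest.  Each channel is

    baseline_velocity * (1 + pulsatility * cardiac(t))
        + response(t, channel) + Gaussian noise

where ``cardiac`` is a per-beat-centred raised-cosine systolic pulse with
exponential diastolic decay at a jittered heart rate, and ``response``
rises after the cue to a peak at ``response_latency_s`` and returns to
zero by the end of the trial.  The left-minus-right response asymmetry is
calibrated analytically so that the noise-free analysis pipeline recovers
``true_li`` — ground truth is defined operationally as the quantity the
pipeline estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .epochs import EpochSpec
from .recording import Recording, TRIAL_START
from .stats import SUBGROUPS, HandednessRecord, SubjectOutcome, subgroup_label

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_session",
    "simulate_cohort",
    "inject_artifact",
    "calibrate_asymmetry",
]

#: phase fraction of the cardiac cycle occupied by the systolic upstroke
_SYSTOLE_FRAC = 0.15
#: diastolic decay constant as a fraction of the cycle
_DIASTOLE_TAU = 0.30


@dataclass
class SimulationParams:
    """Generative settings for one session (see module docstring)."""

    n_trials: int = 24
    fs_raw: float = 100.0
    watch_s: float = 12.0
    talk_s: float = 10.0
    rest_s: float = 8.0
    baseline_velocity: float = 100.0
    heart_rate_bpm: float = 95.0
    heart_rate_sd: float = 5.0
    pulsatility: float = 0.25
    response_amp: float = 3.0
    true_li: float = 0.0
    response_latency_s: float = 9.0
    noise_sd: float = 0.8
    amp_jitter_sd: float = 0.2
    asym_trial_sd: float = 2.5
    p_dropout_trial: float = 0.05
    p_spike_trial: float = 0.05
    artifact_run_length: int = 2
    analysis_fs: float = 25.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.watch_s, self.talk_s, self.rest_s) <= 0:
            raise ValueError("trial phase durations must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fs_raw <= 0 or self.analysis_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if self.fs_raw < self.analysis_fs:
            raise ValueError("fs_raw must be >= analysis_fs")
        if self.fs_raw < 4.0 * self.heart_rate_bpm / 60.0:
            raise ValueError("fs_raw must be >= 4x the cardiac frequency")
        if self.baseline_velocity <= 0:
            raise ValueError("baseline_velocity must be positive")
        for name in ("p_dropout_trial", "p_spike_trial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.response_latency_s < self.talk_s + self.rest_s:
            raise ValueError("response_latency_s must fall after the cue, "
                             "before the trial ends")
        if self.artifact_run_length < 0:
            raise ValueError("artifact_run_length must be >= 0")

    @property
    def trial_s(self) -> float:
        return self.watch_s + self.talk_s + self.rest_s


@dataclass
class GroundTruth:
    """What the simulator actually injected (for test bookkeeping)."""

    true_li: float
    asymmetry: float  # calibrated left-minus-right response amplitude
    artifacts: dict[int, list[tuple[str, list[int]]]] = field(default_factory=dict)
    beat_times_s: list[float] = field(default_factory=list)
    trial_amplitudes: list[tuple[float, float]] = field(default_factory=list)


def _response_shape(tau: np.ndarray, latency: float, total: float) -> np.ndarray:
    """Smooth rise to 1 at ``latency``, back to 0 at ``total``; 0 outside."""
    s = np.zeros_like(tau)
    rise = (tau >= 0) & (tau < latency)
    fall = (tau >= latency) & (tau < total)
    s[rise] = np.sin(0.5 * np.pi * tau[rise] / latency) ** 2
    s[fall] = np.sin(0.5 * np.pi * (total - tau[fall]) / (total - latency)) ** 2
    return s


def _cardiac_waveform(phase: np.ndarray) -> np.ndarray:
    """Raised-cosine systolic peak, exponential diastolic decay; phase in [0,1)."""
    w = np.empty_like(phase)
    up = phase < _SYSTOLE_FRAC
    w[up] = 0.5 * (1.0 - np.cos(np.pi * phase[up] / _SYSTOLE_FRAC))
    w[~up] = np.exp(-(phase[~up] - _SYSTOLE_FRAC) / _DIASTOLE_TAU)
    return w


def calibrate_asymmetry(params: SimulationParams,
                        spec: EpochSpec | None = None) -> float:
    """Left-minus-right response amplitude whose noise-free pipeline output
    equals ``params.true_li``.

    Uses the closed-form map through normalization (each channel scaled to
    mean 100), baseline correction and the 2 s window mean at the response
    peak; cardiac pulsatility is per-beat zero-mean so it drops out.
    """
    spec = spec or EpochSpec()
    fs = params.analysis_fs
    n_ep = int(round(params.trial_s * fs))
    t_post_cue = np.arange(n_ep) / fs - params.watch_s
    total = params.talk_s + params.rest_s
    s = _response_shape(t_post_cue, params.response_latency_s, total)
    s_mean = s.mean()
    half = spec.li_window_s / 2.0
    win = ((t_post_cue >= params.response_latency_s - half - 1e-12)
           & (t_post_cue <= params.response_latency_s + half + 1e-12))
    k_w = s[win].mean()
    b = params.response_amp
    v0 = params.baseline_velocity

    def predicted_li(delta: float) -> float:
        amp_l = b + delta / 2.0
        amp_r = b - delta / 2.0
        f_l = 100.0 / (v0 + amp_l * s_mean)
        f_r = 100.0 / (v0 + amp_r * s_mean)
        return k_w * (f_l * amp_l - f_r * amp_r)

    target = params.true_li
    lo, hi = -8.0 * (abs(target) + b + 1.0), 8.0 * (abs(target) + b + 1.0)
    return float(brentq(lambda d: predicted_li(d) - target, lo, hi, xtol=1e-12))


def _spike_value(params: SimulationParams) -> float:
    # comfortably above any plausible mean + 4 SD for these signal levels
    return params.baseline_velocity * (1.0 + params.pulsatility) + 60.0


def simulate_session(params: SimulationParams | None = None
                     ) -> tuple[Recording, GroundTruth]:
    """Generate one session; fully reproducible from ``params.seed``."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    fs = params.fs_raw
    n_trial = int(round(params.trial_s * fs))
    n = params.n_trials * n_trial + int(round(fs))  # 1 s tail padding
    duration = n / fs

    # cardiac pulse train, centred per beat so it cancels in normalization
    beat_times = []
    t = 0.0
    while t < duration + 2.0:
        beat_times.append(t)
        hr = float(np.clip(rng.normal(params.heart_rate_bpm,
                                      params.heart_rate_sd), 40.0, 180.0))
        t += 60.0 / hr
    cardiac = np.zeros(n)
    for t0, t1 in zip(beat_times, beat_times[1:]):
        i0 = int(math.ceil(t0 * fs))
        i1 = min(int(math.ceil(t1 * fs)), n)
        if i1 <= i0:
            continue
        phase = (np.arange(i0, i1) / fs - t0) / (t1 - t0)
        w = _cardiac_waveform(phase)
        cardiac[i0:i1] = w - w.mean()

    base = params.baseline_velocity * (1.0 + params.pulsatility * cardiac)
    left = base + rng.normal(0.0, params.noise_sd, n)
    right = base + rng.normal(0.0, params.noise_sd, n)

    delta = calibrate_asymmetry(params)
    total = params.talk_s + params.rest_s
    n_resp = int(round(total * fs))
    tau = np.arange(n_resp) / fs
    s = _response_shape(tau, params.response_latency_s, total)
    markers = []
    trial_amps = []
    sigma = math.sqrt(math.log(1.0 + params.amp_jitter_sd ** 2))
    for k in range(params.n_trials):
        m = k * n_trial
        markers.append((m, TRIAL_START))
        g = float(rng.lognormal(-0.5 * sigma ** 2, sigma))
        eps = float(rng.normal(0.0, params.asym_trial_sd))
        asym = g * delta + eps
        amp_l = g * params.response_amp + asym / 2.0
        amp_r = g * params.response_amp - asym / 2.0
        trial_amps.append((amp_l, amp_r))
        cue = m + int(round(params.watch_s * fs))
        left[cue:cue + n_resp] += amp_l * s
        right[cue:cue + n_resp] += amp_r * s

    # artifacts: runs sized so they survive downsampling to the analysis rate
    run_raw = params.artifact_run_length * max(
        1, int(round(fs / params.analysis_fs)))
    artifacts: dict[int, list[tuple[str, list[int]]]] = {}
    for k in range(params.n_trials):
        m = k * n_trial
        for kind, p in (("dropout", params.p_dropout_trial),
                        ("spike", params.p_spike_trial)):
            if run_raw == 0 or rng.random() >= p:
                continue
            start = m + int(rng.integers(0, n_trial - run_raw))
            chan = left if rng.random() < 0.5 else right
            idx = list(range(start, start + run_raw))
            chan[idx] = 0.0 if kind == "dropout" else _spike_value(params)
            artifacts.setdefault(k + 1, []).append((kind, idx))

    rec = Recording(subject_id="sim", fs=fs, left=left, right=right,
                    markers=markers, meta={"simulated": True})
    gt = GroundTruth(true_li=params.true_li, asymmetry=delta,
                     artifacts=artifacts, beat_times_s=beat_times,
                     trial_amplitudes=trial_amps)
    return rec, gt


def inject_artifact(rec: Recording, trial: int, kind: str,
                    n_points: int) -> Recording:
    """Overwrite ``n_points`` consecutive left-channel samples mid-talk-phase
    of the given 1-based trial with dropout (zeros) or spike values.

    ``n_points=0`` returns an unchanged copy.  Spike values are placed at
    the trial mean plus 8 trial SDs so they always exceed the 4 SD
    screening bound; dropout zeros are always flagged by the <= 0 rule.
    """
    if kind not in ("dropout", "spike"):
        raise ValueError("kind must be 'dropout' or 'spike'")
    if not 1 <= trial <= len(rec.markers):
        raise ValueError(f"invalid trial {trial}: session has "
                         f"{len(rec.markers)} trials")
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    out = replace(rec, left=rec.left.copy(), right=rec.right.copy(),
                  markers=list(rec.markers))
    if n_points == 0:
        return out
    m = rec.markers[trial - 1][0]
    start = m + int(round(17.0 * rec.fs))  # 5 s into the talk phase
    stop = start + n_points
    if stop > rec.n_samples:
        raise ValueError("artifact would extend beyond the record")
    if kind == "dropout":
        out.left[start:stop] = 0.0
    else:
        trial_end = min(m + int(round(30.0 * rec.fs)), rec.n_samples)
        seg = rec.left[m:trial_end]
        out.left[start:stop] = seg.mean() + 8.0 * seg.std(ddof=1)
    return out


def _largest_remainder(proportions: np.ndarray, n: int) -> np.ndarray:
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


_DEFAULT_LI_DISTRIBUTIONS = {
    "typical": (2.5, 3.8),
    "late_bloomer": (1.0, 3.8),
    "plateau": (-0.5, 3.3),
    "persistent_sli": (0.5, 3.3),
}

_N_LANGUAGE_MEASURES = 9


def _draw_zscores(rng: np.random.Generator, impaired: bool) -> dict[str, float]:
    """Nine language z-scores consistent with the impairment rule
    (impaired: >= 2 measures strictly below -1; typical: at most 1)."""
    z = rng.normal(0.2, 0.8, _N_LANGUAGE_MEASURES)
    if impaired:
        n_fail = 2 + int(rng.integers(0, 3))
        which = rng.choice(_N_LANGUAGE_MEASURES, size=n_fail, replace=False)
        z[which] = -1.0 - np.abs(rng.normal(0.8, 0.4, n_fail)) - 0.01
        others = np.setdiff1d(np.arange(_N_LANGUAGE_MEASURES), which)
        z[others] = np.maximum(z[others], -0.99)
    else:
        below = np.flatnonzero(z < -1.0)
        if below.size > 1:
            z[below[1:]] = -0.9
    return {f"measure_{i + 1}": float(v) for i, v in enumerate(z)}


def _draw_handedness(rng: np.random.Generator) -> HandednessRecord:
    right = int(rng.binomial(9, 0.88))
    total = 21
    return HandednessRecord(
        ehi_right_items=right, ehi_left_items=9 - right,
        qhp_right_reaches=int(rng.binomial(total, 0.78)),
        qhp_total_reaches=total,
    )


def simulate_cohort(
    n_subjects: int,
    subgroup_mix: Sequence[float] | dict[str, float] | None = None,
    li_distributions: dict[str, tuple[float, float]] | None = None,
    params: SimulationParams | None = None,
    seed: Optional[int] = None,
) -> tuple[list[Recording], list[SubjectOutcome], list[GroundTruth]]:
    """Generate a cohort of sessions with subgroup labels and consistent
    language z-scores.

    ``subgroup_mix`` gives proportions over (typical, late_bloomer,
    plateau, persistent_sli); counts use deterministic largest-remainder
    rounding.  Per-subject true LI is drawn from the subgroup's
    (mean, sd).  Outcome rows carry the true LI; measured LIs come from
    running the analysis pipeline on the returned recordings.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if subgroup_mix is None:
        mix = np.array([36, 10, 6, 5], dtype=float) / 57.0
    elif isinstance(subgroup_mix, dict):
        mix = np.array([subgroup_mix.get(g, 0.0) for g in SUBGROUPS], dtype=float)
    else:
        mix = np.asarray(subgroup_mix, dtype=float)
    if mix.size != 4 or (mix < 0).any():
        raise ValueError("subgroup_mix must be 4 non-negative proportions")
    if mix.sum() <= 0:
        raise ValueError("subgroup_mix must not be all zero")
    mix = mix / mix.sum()
    li_dist = dict(_DEFAULT_LI_DISTRIBUTIONS)
    if li_distributions:
        li_dist.update(li_distributions)
    template = params or SimulationParams()

    counts = _largest_remainder(mix, n_subjects)
    labels = [g for g, c in zip(SUBGROUPS, counts) for _ in range(int(c))]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects + 1)
    rng = np.random.default_rng(children[-1])

    recordings, outcomes, truths = [], [], []
    for i, group in enumerate(labels):
        mu, sd = li_dist[group]
        true_li = float(rng.normal(mu, sd))
        sub_seed = int(children[i].generate_state(1)[0])
        p = replace(template, true_li=true_li, seed=sub_seed)
        rec, gt = simulate_session(p)
        sid = f"sub{i + 1:03d}"
        rec = replace(rec, subject_id=sid)
        late = group in ("late_bloomer", "persistent_sli")
        impaired = group in ("plateau", "persistent_sli")
        outcomes.append(SubjectOutcome(
            subject_id=sid, late_talker_20m=late, impaired_4y=impaired,
            subgroup=subgroup_label(late, impaired),
            language_zscores=_draw_zscores(rng, impaired),
            li=true_li, handedness=_draw_handedness(rng),
        ))
        recordings.append(rec)
        truths.append(gt)
    return recordings, outcomes, truths
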