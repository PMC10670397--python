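"""Synthetic multimodal NICU recordings with known sleep-state structure.

Every generator is a pure function of a :class:`~neosleep.config.SimConfig`
(and, for the cohort helper, a subject index), so a fixed seed yields
bit-identical output.  The simulator reproduces the statistical structure the
analysis pipeline assumes rather than physiological waveform realism:

* a semi-Markov hypnogram with geometric bout lengths whose stationary state
  mix matches the configured fractions (default AS 72 %, QS 12 %, CTW 16 %);
* R-peak event times with state-dependent mean/SD of the inter-beat interval
  and Poisson-arriving heart-rate decelerations;
* a respiratory-effort waveform built from concatenated asymmetric breath
  templates with state-dependent rate regularity and amplitude;
* a nonnegative motion-count trace of Poisson-arriving movement bursts whose
  rate and amplitude depend on state (CTW >> AS >> QS);
* optionally, an ECG-like trace with a QRS template at each R time, for
  exercising R-peak detection and ECG waveform features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EPOCH_S, STATES, SimConfig, StateParams
from .io import Recording, write_recording

__all__ = [
    "Hypnogram",
    "generate_hypnogram",
    "generate_rpeaks",
    "generate_respiration",
    "generate_motion",
    "generate_ecg_waveform",
    "simulate_recording",
    "simulate_cohort",
]

# fixed per-purpose stream ids so the generators draw independent substreams
_STREAMS = {"hypnogram": 1, "rpeaks": 2, "resp": 3, "motion": 4, "ecg": 5, "unknown": 6}


def _rng(config: SimConfig, purpose: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[purpose], config.seed])


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch state labels; epochs are fixed 30-s windows."""

    labels: tuple[str, ...]
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(STATES)
        if bad:
            raise ValueError(f"hypnogram labels must be in {STATES}, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_s

    def state_at(self, t: float) -> str:
        i = min(int(t // self.epoch_s), len(self.labels) - 1)
        return self.labels[i]

    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {s: sum(lab == s for lab in self.labels) / n for s in STATES}


def _bout_entry_weights(config: SimConfig) -> np.ndarray:
    """Entry weights making the semi-Markov chain's time fractions match.

    Bouts of state ``s`` should occur with probability ``q_s ∝ f_s / L_s``
    (fraction over mean bout length).  The embedded chain forbids immediate
    self-transitions, which biases the realized bout-type distribution, so
    the weights are corrected by a deterministic fixed-point iteration on the
    chain's stationary distribution.
    """
    f = np.array([config.state_fractions[s] for s in STATES])
    L = np.array([config.mean_bout_epochs[s] for s in STATES])
    target = f / L
    target /= target.sum()
    w = target.copy()
    for _ in range(200):
        P = np.tile(w, (3, 1))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(P.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat = np.abs(stat) / np.abs(stat).sum()
        w = w * target / np.maximum(stat, 1e-12)
        w /= w.sum()
    return w


def generate_hypnogram(config: SimConfig) -> Hypnogram:
    """Draw a semi-Markov state sequence with geometric bout lengths.

    Bout lengths are geometric with the configured per-state means.  The
    bout-type draw is mildly self-correcting: entry weights are tilted
    toward states currently under-represented relative to the target mix,
    which pins the realized state fractions to the configured ones far
    faster than an i.i.d. bout-type chain (whose fraction still fluctuates
    by several percent after hundreds of bouts) while leaving bout-length
    statistics untouched.
    """
    rng = _rng(config, "hypnogram")
    w = _bout_entry_weights(config)
    L = np.array([config.mean_bout_epochs[s] for s in STATES])
    target = np.array([config.state_fractions[s] for s in STATES])
    counts = np.zeros(3)
    labels: list[int] = []
    cur = int(rng.choice(3, p=w))
    while len(labels) < config.duration_epochs:
        bout = int(rng.geometric(1.0 / L[cur]))
        labels.extend([cur] * bout)
        counts[cur] += bout
        deficit = target - counts / counts.sum()
        p = w * np.exp(25.0 * deficit)
        p[cur] = 0.0
        p /= p.sum()
        cur = int(rng.choice(3, p=p))
    return Hypnogram(labels=tuple(STATES[i] for i in labels[: config.duration_epochs]))


def generate_rpeaks(hypnogram: Hypnogram, config: SimConfig) -> np.ndarray:
    """Generate strictly increasing R-peak times (s) over the hypnogram.

    Inter-beat intervals are Gaussian per state (truncated at half the state
    mean so they stay positive); decelerations arrive as a Poisson process
    with the state's ``decel_rate`` and prolong a short run of 3-6 intervals
    by the factor ``1 + decel_depth``.
    """
    rng = _rng(config, "rpeaks")
    T = hypnogram.duration_s
    times: list[float] = []
    t = 0.0
    decel_left = 0
    while True:
        p: StateParams = config.state_params[hypnogram.state_at(t)]
        rr_s = (p.mean_rr + p.sd_rr * rng.standard_normal()) / 1000.0
        rr_s = max(rr_s, 0.5 * p.mean_rr / 1000.0)
        if decel_left > 0:
            rr_s *= 1.0 + p.decel_depth
            decel_left -= 1
        elif p.decel_rate > 0 and rng.random() < p.decel_rate * rr_s / 60.0:
            decel_left = int(rng.integers(3, 7))
        t += rr_s
        if t >= T:
            break
        times.append(t)
    return np.asarray(times)


def _breath_samples(
    starts: np.ndarray,
    periods: np.ndarray,
    amps: np.ndarray,
    t: np.ndarray,
    inhale_frac: float = 0.4,
) -> np.ndarray:
    """Evaluate the concatenated breath waveform at sample times ``t``.

    Each breath is a smooth asymmetric oscillation around zero: a rising
    half-cosine (trough to peak) over the inhale limb and a falling
    half-cosine over the longer exhale limb, peak-to-trough amplitude
    ``amps[i]``.
    """
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    phase = (t - starts[idx]) / periods[idx]
    phase = np.clip(phase, 0.0, 1.0)
    a = amps[idx]
    up = phase < inhale_frac
    x = np.empty_like(t)
    x[up] = -0.5 * a[up] + a[up] * 0.5 * (1 - np.cos(np.pi * phase[up] / inhale_frac))
    ph = (phase[~up] - inhale_frac) / (1 - inhale_frac)
    x[~up] = 0.5 * a[~up] - a[~up] * 0.5 * (1 - np.cos(np.pi * ph))
    return x


def generate_respiration(hypnogram: Hypnogram, config: SimConfig) -> np.ndarray:
    """Generate the respiratory-effort waveform sampled at ``resp_rate``."""
    rng = _rng(config, "resp")
    T = hypnogram.duration_s
    starts, periods, amps = [], [], []
    t = 0.0
    while t < T:
        p = config.state_params[hypnogram.state_at(t)]
        base = 60.0 / p.breath_rate
        period = base * (1.0 + p.breath_rate_jitter * rng.standard_normal())
        period = max(period, 0.3 * base)
        amp = p.breath_amp * (1.0 + p.breath_amp_cv * rng.standard_normal())
        amp = max(amp, 0.05 * p.breath_amp)
        starts.append(t)
        periods.append(period)
        amps.append(amp)
        t += period
    n = int(round(T * config.resp_rate))
    ts = np.arange(n) / config.resp_rate
    return _breath_samples(np.asarray(starts), np.asarray(periods), np.asarray(amps), ts)


def generate_motion(hypnogram: Hypnogram, config: SimConfig) -> np.ndarray:
    """Generate the nonnegative motion-count trace sampled at ``motion_rate``.

    Movement bursts arrive as a per-epoch Poisson process with the state's
    ``motion_burst_rate``; each burst is a half-sine pulse of 0.25-1.5 s with
    exponentially distributed amplitude (mean ``motion_burst_amp``).  The
    trace is exactly zero between bursts.
    """
    rng = _rng(config, "motion")
    rate = config.motion_rate
    n = int(round(hypnogram.duration_s * rate))
    x = np.zeros(n)
    for i, lab in enumerate(hypnogram.labels):
        p = config.state_params[lab]
        lam = p.motion_burst_rate * (hypnogram.epoch_s / 60.0)
        for _ in range(rng.poisson(lam)):
            start = (i + rng.random()) * hypnogram.epoch_s
            dur = rng.uniform(0.25, 1.5)
            amp = rng.exponential(p.motion_burst_amp)
            a = int(start * rate)
            b = min(n, int((start + dur) * rate) + 1)
            if a >= n:
                continue
            tt = np.arange(a, b) / rate
            x[a:b] += amp * np.sin(np.pi * np.clip((tt - start) / dur, 0, 1))
    return np.maximum(x, 0.0)


def generate_ecg_waveform(
    rpeak_times: np.ndarray, config: SimConfig, duration_s: float
) -> np.ndarray:
    """Render an ECG-like trace: Gaussian QRS templates on white noise.

    The template apex coincides with each R time to sample precision, so a
    noise-free trace round-trips through R-peak detection exactly.
    """
    rng = _rng(config, "ecg")
    rate = config.ecg_rate
    n = int(round(duration_s * rate))
    x = rng.normal(0.0, config.ecg_noise_sd, n) if config.ecg_noise_sd > 0 else np.zeros(n)
    if len(rpeak_times) == 0:
        return x
    rt = np.asarray(rpeak_times, dtype=np.float64)
    if np.any(np.diff(rt) <= 0):
        raise ValueError("rpeak_times must be strictly increasing")
    sigma = 0.008  # QRS width ~8 ms SD
    half = int(0.03 * rate)
    offs = np.arange(-half, half + 1)
    for t in rt:
        c = int(round(t * rate))
        idx = c + offs
        ok = (idx >= 0) & (idx < n)
        x[idx[ok]] += np.exp(-0.5 * ((idx[ok] / rate - t) / sigma) ** 2)
    return x


def simulate_recording(
    config: SimConfig,
    subject_id: str = "S1",
    include_ecg_waveform: bool = True,
    out_dir: str | Path | None = None,
) -> Recording:
    """Simulate one full recording; optionally write it to ``out_dir``.

    The returned :class:`~neosleep.io.Recording` carries the hypnogram as its
    annotation table (with ``unknown_fraction`` of epochs relabeled
    ``Unknown`` to exercise exclusion logic), R-peak times, respiratory
    effort, motion counts and — unless disabled — the rendered ECG trace.
    """
    hyp = generate_hypnogram(config)
    rpeaks = generate_rpeaks(hyp, config)
    resp = generate_respiration(hyp, config)
    motion = generate_motion(hyp, config)
    ecg = (
        generate_ecg_waveform(rpeaks, config, hyp.duration_s)
        if include_ecg_waveform
        else None
    )
    labels = list(hyp.labels)
    if config.unknown_fraction > 0:
        rng = _rng(config, "unknown")
        mask = rng.random(len(labels)) < config.unknown_fraction
        labels = ["Unknown" if m else lab for lab, m in zip(labels, mask)]
    ann = pd.DataFrame(
        {
            "epoch_index": np.arange(len(labels)),
            "onset_s": np.arange(len(labels)) * EPOCH_S,
            "label": labels,
        }
    )
    rec = Recording(
        subject_id=subject_id,
        annotations=ann,
        ecg=ecg,
        resp=resp,
        motion=motion,
        rpeak_times=rpeaks,
        ecg_rate=config.ecg_rate,
        resp_rate=config.resp_rate,
        motion_rate=config.motion_rate,
        meta={"seed": config.seed},
    )
    if out_dir is not None:
        write_recording(rec, out_dir)
    return rec


def simulate_cohort(
    config: SimConfig,
    n_subjects: int = 8,
    subject_cv: float = 0.05,
    include_ecg_waveform: bool = True,
) -> list[Recording]:
    """Simulate a cohort with mild between-subject physiological variation.

    Each subject gets a seed derived from ``config.seed`` and multiplicative
    lognormal-ish offsets (CV ``subject_cv``) on mean RR, breathing rate and
    movement-burst rate, shared across that subject's states — emulating the
    between-infant differences that make leave-one-subject-out validation a
    meaningful test of generalization.
    """
    recs = []
    for j in range(n_subjects):
        srng = np.random.default_rng([7, config.seed, j])
        rr_f, br_f, mo_f = np.exp(subject_cv * srng.standard_normal(3))
        params = {
            s: replace(
                p,
                mean_rr=p.mean_rr * rr_f,
                breath_rate=p.breath_rate * br_f,
                motion_burst_rate=p.motion_burst_rate * mo_f,
            )
            for s, p in config.state_params.items()
        }
        sub_cfg = replace(
            config,
            state_params=params,
            seed=int(np.random.SeedSequence([11, config.seed, j]).generate_state(1)[0] % (2**31)),
        )
        recs.append(
            simulate_recording(
                sub_cfg, subject_id=f"S{j + 1}", include_ecg_waveform=include_ecg_waveform
            )
        )
    return recs
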