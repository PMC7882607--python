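"""Synthetic multichannel EEG cohorts.

Generates surrogate cohorts with the statistical structure the downstream
analysis relies on: subject-specific spectral fingerprints, an age-group
contrast (alpha-peak shift plus occipital alpha attenuation in the elderly
group), cross-channel shared sources that induce functional connectivity,
and injectable artifacts (blinks, muscle bursts, jumps, clips) with a
ground-truth event log.

Each channel is a mixture of narrow-band stochastic oscillators — damped
second-order autoregressive resonators, one shared source per band plus one
independent oscillator per channel per band — on top of 1/f-shaped
background noise and a white-noise floor.  The shared sources create the
coherence/MI structure between channels; the per-subject random gain
pattern is the identity fingerprint; small condition-specific gain
modulations keep conditions of one subject more alike than different
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datasets import EEGDataset, TrialSet

BAND_NAMES = ("theta", "alpha", "beta")
_BURN_IN = 500  # samples discarded so resonators reach stationarity


@dataclass
class CohortConfig:
    """Cohort-level generation parameters.

    Defaults mirror the study design this generator emulates: 22 young and
    23 elderly subjects, 64 channels sampled at 1,000 Hz, 1,500 ms epochs,
    six stimulus conditions with 80 trials each; elderly subjects have an
    alpha peak shifted 1 Hz downwards and occipital alpha gains attenuated
    by a factor 0.7.
    """

    n_young: int = 22
    n_elderly: int = 23
    n_channels: int = 64
    fs: float = 1000.0
    trial_len_ms: float = 1500.0
    n_trials_per_condition: int = 80
    conditions: tuple[str, ...] = (
        "car_high", "face_high", "scrambled_high",
        "car_low", "face_low", "scrambled_low",
    )
    alpha_peak_young_hz: float = 10.0
    alpha_peak_elderly_hz: float = 9.0
    alpha_peak_sd_hz: float = 0.5
    occipital_attenuation: float = 0.7
    occipital_fraction: float = 0.25
    theta_hz: float = 5.0
    beta_hz: float = 20.0
    resonator_bandwidth_hz: float = 2.0
    background_exponent: float = 1.0
    background_scale: float = 1.0
    white_noise_frac: float = 0.1
    subject_gain_sd: float = 0.4
    condition_gain_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.trial_len_ms * self.fs / 1000.0
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(
                f"trial_len_ms × fs must give a whole positive number of samples, got {n}"
            )
        if self.n_young <= 0 or self.n_elderly <= 0:
            raise ValueError("both groups need at least one subject")
        if not 0 < self.occipital_attenuation <= 1:
            raise ValueError("occipital_attenuation must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_ms * self.fs / 1000.0))

    @property
    def occipital_channels(self) -> np.ndarray:
        """Indices of the designated 'occipital' channel block (last fraction)."""
        n_occ = max(1, int(round(self.occipital_fraction * self.n_channels)))
        return np.arange(self.n_channels - n_occ, self.n_channels)


@dataclass
class SubjectSpec:
    """Generative parameters of one subject.

    ``mixing`` (n_bands × n_channels) weights the shared band sources into
    each channel — the connectivity-inducing part.  ``band_gains`` (same
    shape) scales the channel-independent oscillators — the per-subject
    spectral fingerprint.  Identical spec + seed gives bit-identical trials.
    """

    subject_id: str
    group: str
    alpha_peak_hz: float
    band_gains: np.ndarray
    mixing: np.ndarray
    noise_sd: float
    seed: int

    def validate(self, cfg: CohortConfig) -> None:
        if not 0 < self.alpha_peak_hz < cfg.fs / 2:
            raise ValueError(
                f"alpha_peak_hz={self.alpha_peak_hz} outside (0, Nyquist={cfg.fs / 2})"
            )
        for name, arr in (("band_gains", self.band_gains), ("mixing", self.mixing)):
            arr = np.asarray(arr)
            if arr.shape != (len(BAND_NAMES), cfg.n_channels):
                raise ValueError(
                    f"{name} must have shape ({len(BAND_NAMES)}, {cfg.n_channels}), got {arr.shape}"
                )
        # no dead channels: every channel must receive some signal
        total = np.abs(self.mixing).sum(axis=0) + np.abs(self.band_gains).sum(axis=0)
        if np.any(total == 0) and self.noise_sd == 0:
            raise ValueError("channel with no source contribution and zero noise")


@dataclass
class ArtifactSpec:
    """Rates and shapes of injectable artifacts.

    Rates are events per second (blinks, muscle bursts) or per-trial
    probabilities (jumps, clips); amplitudes are expressed in units of the
    per-channel signal SD so injection adapts to the signal scale.
    """

    blink_rate: float = 0.2
    blink_amp_sd: float = 10.0
    blink_duration_s: float = 0.3
    frontal_fraction: float = 0.1
    muscle_rate: float = 0.1
    muscle_band: tuple[float, float] = (120.0, 140.0)
    muscle_amp_sd: float = 5.0
    muscle_duration_s: float = 0.2
    jump_prob: float = 0.02
    jump_amp_sd: float = 50.0
    clip_prob: float = 0.02
    clip_duration_s: float = 0.03

    def __post_init__(self) -> None:
        if min(self.blink_rate, self.muscle_rate, self.jump_prob, self.clip_prob) < 0:
            raise ValueError("artifact rates and probabilities must be ≥ 0")
        if self.clip_duration_s <= 0:
            raise ValueError("clip duration must be positive")


# ------------------------------------------------------------------ sources


def _resonator(rng: np.random.Generator, n: int, f0: float, fs: float,
               bandwidth_hz: float, size: int = 1) -> np.ndarray:
    """Damped stochastic AR(2) resonator(s) with spectral peak at ``f0``.

    Returns an array of shape (size, n), each row standardized to unit SD.
    """
    r = np.exp(-np.pi * bandwidth_hz / fs)
    theta = 2 * np.pi * f0 / fs
    a = [1.0, -2 * r * np.cos(theta), r * r]
    e = rng.standard_normal((size, n + _BURN_IN))
    y = sps.lfilter([1.0], a, e, axis=-1)[:, _BURN_IN:]
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, size: int) -> np.ndarray:
    """1/f^exponent-shaped Gaussian noise, unit SD per row."""
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid DC blow-up
    spec *= f ** (-exponent / 2.0)
    y = np.fft.irfft(spec, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


# ------------------------------------------------------------- generation


def _condition_modulation(spec: SubjectSpec, cfg: CohortConfig, condition: str) -> np.ndarray:
    """Deterministic per-condition multiplicative gain pattern (n_bands × n_ch)."""
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}; known: {cfg.conditions}")
    ci = cfg.conditions.index(condition)
    rng = np.random.default_rng([abs(spec.seed), 7919, ci])
    z = rng.standard_normal((len(BAND_NAMES), cfg.n_channels))
    return np.exp(cfg.condition_gain_sd * z)


def generate_subject_trials(spec: SubjectSpec, cfg: CohortConfig, condition: str) -> TrialSet:
    """Generate all trials of one subject under one condition.

    Each trial: per-band shared source mixed into channels via ``mixing``,
    per-channel independent oscillators scaled by ``band_gains`` (both
    modulated by the condition pattern), plus 1/f background and white noise.
    """
    spec.validate(cfg)
    freqs = {"theta": cfg.theta_hz, "alpha": spec.alpha_peak_hz, "beta": cfg.beta_hz}
    for name, f0 in freqs.items():
        if not 0 < f0 < cfg.fs / 2:
            raise ValueError(f"{name} center frequency {f0} Hz is outside (0, Nyquist)")

    ci = cfg.conditions.index(condition)
    rng = np.random.default_rng([abs(spec.seed), 104729, ci])
    mod = _condition_modulation(spec, cfg, condition)
    gains = np.asarray(spec.band_gains) * mod
    mixing = np.asarray(spec.mixing) * mod

    n, n_ch = cfg.n_samples, cfg.n_channels
    data = np.empty((cfg.n_trials_per_condition, n_ch, n))
    for t in range(cfg.n_trials_per_condition):
        y = np.zeros((n_ch, n))
        for b, band in enumerate(BAND_NAMES):
            shared = _resonator(rng, n, freqs[band], cfg.fs, cfg.resonator_bandwidth_hz)[0]
            indep = _resonator(rng, n, freqs[band], cfg.fs, cfg.resonator_bandwidth_hz, size=n_ch)
            y += mixing[b][:, None] * shared[None, :] + gains[b][:, None] * indep
        if cfg.background_scale > 0:
            y += cfg.background_scale * _pink_noise(rng, n, cfg.background_exponent, n_ch)
        if spec.noise_sd > 0:
            y += spec.noise_sd * rng.standard_normal((n_ch, n))
        data[t] = y

    return TrialSet(
        data=data,
        fs=cfg.fs,
        channel_names=[f"ch{i:02d}" for i in range(n_ch)],
        subject=spec.subject_id,
        group=spec.group,
        condition=condition,
    )


def make_subject_specs(cfg: CohortConfig) -> list[SubjectSpec]:
    """Draw one SubjectSpec per subject from group-level distributions."""
    rng = np.random.default_rng([abs(cfg.seed), 15485863])
    occ = cfg.occipital_channels
    n_ch = cfg.n_channels
    frontal = np.arange(max(1, int(round(0.25 * n_ch))))

    # base spatial profiles of the shared sources
    base_mix = np.full((len(BAND_NAMES), n_ch), 0.2)
    base_mix[BAND_NAMES.index("theta"), frontal] = 0.6
    base_mix[BAND_NAMES.index("alpha"), occ] = 1.0
    base_mix[BAND_NAMES.index("alpha"), : occ[0]] = 0.3
    base_mix[BAND_NAMES.index("beta")] = 0.4
    base_gain = np.full((len(BAND_NAMES), n_ch), 0.5)

    specs: list[SubjectSpec] = []
    groups = ["young"] * cfg.n_young + ["elderly"] * cfg.n_elderly
    for i, group in enumerate(groups):
        mean = cfg.alpha_peak_young_hz if group == "young" else cfg.alpha_peak_elderly_hz
        peak = float(np.clip(rng.normal(mean, cfg.alpha_peak_sd_hz), 1.0, cfg.fs / 2 - 1.0))
        fingerprint = np.exp(cfg.subject_gain_sd * rng.standard_normal((len(BAND_NAMES), n_ch)))
        gains = base_gain * fingerprint
        mixing = base_mix * np.exp(0.2 * rng.standard_normal((len(BAND_NAMES), n_ch)))
        if group == "elderly":
            a = BAND_NAMES.index("alpha")
            gains[a, occ] *= cfg.occipital_attenuation
            mixing[a, occ] *= cfg.occipital_attenuation
        specs.append(
            SubjectSpec(
                subject_id=f"S{i:03d}",
                group=group,
                alpha_peak_hz=peak,
                band_gains=gains,
                mixing=mixing,
                noise_sd=cfg.white_noise_frac,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_cohort(cfg: CohortConfig) -> EEGDataset:
    """Generate the full cohort: all subjects × conditions × trials.

    A pure function of the configuration including its master seed.
    """
    ds = EEGDataset()
    for spec in make_subject_specs(cfg):
        for cond in cfg.conditions:
            ds.add(generate_subject_trials(spec, cfg, cond))
    return ds


# -------------------------------------------------------------- artifacts


def inject_artifacts(trials: TrialSet, art: ArtifactSpec, seed: int
                     ) -> tuple[TrialSet, pd.DataFrame]:
    """Inject artifacts into a copy of ``trials`` with a ground-truth log.

    Returns the modified copy and a table with one row per injected event:
    trial, channel, start, end (0-based half-open sample range), kind.
    """
    if not np.all(np.isfinite(trials.data)):
        raise ValueError("input trials contain non-finite values")
    if art.muscle_band[1] >= trials.fs / 2:
        raise ValueError(
            f"muscle band upper edge {art.muscle_band[1]} Hz is at or above Nyquist"
        )
    out = trials.copy()
    rng = np.random.default_rng(abs(seed))
    fs, n = trials.fs, trials.n_samples
    dur_s = n / fs
    sd = trials.data.std(axis=2)  # (n_trials, n_ch)
    events: list[dict] = []

    n_frontal = max(1, int(round(art.frontal_fraction * trials.n_channels)))
    blink_len = int(round(art.blink_duration_s * fs))
    muscle_len = int(round(art.muscle_duration_s * fs))
    clip_len = int(round(art.clip_duration_s * fs))

    for t in range(trials.n_trials):
        for _ in range(rng.poisson(art.blink_rate * dur_s)):
            if blink_len >= n:
                continue
            start = int(rng.integers(0, n - blink_len))
            wave = np.sin(np.pi * np.arange(blink_len) / blink_len) ** 2
            for ch in range(n_frontal):
                out.data[t, ch, start:start + blink_len] += art.blink_amp_sd * sd[t, ch] * wave
                events.append(dict(trial=t, channel=ch, start=start,
                                   end=start + blink_len, kind="blink"))
        for _ in range(rng.poisson(art.muscle_rate * dur_s)):
            if muscle_len >= n:
                continue
            start = int(rng.integers(0, n - muscle_len))
            ch = int(rng.integers(0, trials.n_channels))
            burst = rng.standard_normal(muscle_len)
            sos = sps.butter(4, art.muscle_band, btype="bandpass", fs=fs, output="sos")
            burst = sps.sosfiltfilt(sos, burst)
            bsd = burst.std() or 1.0
            out.data[t, ch, start:start + muscle_len] += (
                art.muscle_amp_sd * sd[t, ch] * burst / bsd
            )
            events.append(dict(trial=t, channel=ch, start=start,
                               end=start + muscle_len, kind="muscle"))
        if rng.random() < art.jump_prob:
            ch = int(rng.integers(0, trials.n_channels))
            pos = int(rng.integers(1, n))
            out.data[t, ch, pos:] += art.jump_amp_sd * sd[t, ch]
            events.append(dict(trial=t, channel=ch, start=pos, end=pos + 1, kind="jump"))
        if rng.random() < art.clip_prob and clip_len < n:
            ch = int(rng.integers(0, trials.n_channels))
            start = int(rng.integers(0, n - clip_len))
            out.data[t, ch, start:start + clip_len] = out.data[t, ch, start]
            events.append(dict(trial=t, channel=ch, start=start,
                               end=start + clip_len, kind="clip"))

    log = pd.DataFrame(events, columns=["trial", "channel", "start", "end", "kind"])
    return out, log
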