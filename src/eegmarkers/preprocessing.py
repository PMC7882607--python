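"""Preprocessing chain for multichannel EEG epochs.

Fixed stage order: band-pass + notch filtering → jump/clip detection and
linear interpolation → muscle-artifact trial rejection → common-average
re-referencing.  A "raw" analysis path simply bypasses all of these.

Detector conventions: all artifact segments are 0-based half-open sample
ranges.  A *jump* is a sample whose first-difference z-score (per channel,
per trial) exceeds the cutoff — a level shift is a spike in the derivative.
A *clip* is a maximal run of constant value lasting at least the time
threshold.  Muscle activity is flagged from the 120–140 Hz band: the
per-trial maximum absolute value of the band-passed signal, z-scored across
trials per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datasets import TrialSet

logger = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    """Thresholds and filter edges of the preprocessing chain.

    ``bandpass_hi`` is clamped just below Nyquist when the sampling rate is
    too low for the default 220 Hz edge.
    """

    bandpass_lo: float = 0.1
    bandpass_hi: float = 220.0
    bandpass_order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0
    jump_z_cutoff: float = 20.0
    clip_time_threshold_s: float = 0.02
    muscle_band: tuple[float, float] = (120.0, 140.0)
    muscle_z_cutoff: float = 5.0

    def validate(self, fs: float) -> None:
        hi = self.effective_hi(fs)
        if not 0 < self.bandpass_lo < hi < fs / 2:
            raise ValueError(
                f"need 0 < lo({self.bandpass_lo}) < hi({hi}) < Nyquist({fs / 2})"
            )
        for name, v in (("jump_z_cutoff", self.jump_z_cutoff),
                        ("clip_time_threshold_s", self.clip_time_threshold_s),
                        ("muscle_z_cutoff", self.muscle_z_cutoff)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    def effective_hi(self, fs: float) -> float:
        return min(self.bandpass_hi, 0.99 * fs / 2)


# ----------------------------------------------------------------- epoching


def epoch_continuous(record: np.ndarray, markers, fs: float, channel_names: list[str],
                     len_ms: float, side: str = "post") -> TrialSet:
    """Cut a continuous (n_channels × n_samples) record into epochs.

    ``side='post'`` takes [marker, marker+n); ``side='pre'`` takes
    [marker−n, marker).  Markers whose window falls outside the record are
    rejected with a logged warning rather than raising.
    """
    record = np.atleast_2d(np.asarray(record, dtype=float))
    if side not in ("pre", "post"):
        raise ValueError("side must be 'pre' or 'post'")
    n = len_ms * fs / 1000.0
    if abs(n - round(n)) > 1e-9 or n <= 0:
        raise ValueError("len_ms × fs must give a whole positive number of samples")
    n = int(round(n))
    total = record.shape[1]
    epochs = []
    for m in np.asarray(markers, dtype=int):
        start = m if side == "post" else m - n
        if start < 0 or start + n > total:
            logger.warning("marker %d: %s-stimulus window [%d, %d) outside record, rejected",
                           m, side, start, start + n)
            continue
        epochs.append(record[:, start:start + n])
    data = np.stack(epochs) if epochs else np.empty((0, record.shape[0], n))
    return TrialSet(data=data, fs=fs, channel_names=channel_names)


# ---------------------------------------------------------------- filtering


def filter_trials(trials: TrialSet, cfg: PreprocConfig) -> TrialSet:
    """Zero-phase band-pass (Butterworth) then 50 Hz notch, per channel."""
    cfg.validate(trials.fs)
    sos = sps.butter(cfg.bandpass_order,
                     [cfg.bandpass_lo, cfg.effective_hi(trials.fs)],
                     btype="bandpass", fs=trials.fs, output="sos")
    padlen = 3 * (sos.shape[0] * 2 + 1)
    if trials.n_samples <= padlen:
        raise ValueError(
            f"trials of {trials.n_samples} samples are shorter than the filter "
            f"warm-up; need more than {padlen} samples"
        )
    out = trials.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=2)
    if cfg.notch_hz and cfg.notch_hz < trials.fs / 2:
        b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=trials.fs)
        out.data = sps.filtfilt(b, a, out.data, axis=2)
    return out


# ---------------------------------------------------------------- detectors


def detect_jumps_clips(trials: TrialSet, cfg: PreprocConfig) -> list[list[list[tuple[int, int]]]]:
    """Detect jump and clip segments per trial and channel.

    Returns ``segments[trial][channel]`` = list of (start, end) half-open
    sample ranges (jumps and clips merged).  An empty result is valid.
    """
    cfg.validate(trials.fs)
    min_run = int(np.ceil(cfg.clip_time_threshold_s * trials.fs))
    out: list[list[list[tuple[int, int]]]] = []
    for t in range(trials.n_trials):
        per_trial: list[list[tuple[int, int]]] = []
        for c in range(trials.n_channels):
            x = trials.data[t, c]
            segs: list[tuple[int, int]] = []
            d = np.diff(x)
            sd = d.std()
            if sd > 0:
                z = (d - d.mean()) / sd
                for i in np.flatnonzero(np.abs(z) > cfg.jump_z_cutoff):
                    # the sample after the offending difference carries the new level
                    segs.append((int(i) + 1, int(i) + 2))
            # maximal constant runs
            change = np.flatnonzero(np.diff(x) != 0)
            bounds = np.concatenate(([0], change + 1, [len(x)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                if e - s >= min_run:
                    segs.append((int(s), int(e)))
            per_trial.append(_merge_segments(segs))
        out.append(per_trial)
    return out


def _merge_segments(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not segs:
        return []
    segs = sorted(segs)
    merged = [segs[0]]
    for s, e in segs[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interpolate_segments(trials: TrialSet, segments) -> TrialSet:
    """Replace flagged samples by linear interpolation between clean neighbors.

    All samples outside the segments are bit-identical to the input.  A
    segment touching both trial edges leaves no anchor on either side; that
    channel is filled with zeros and reported unrecoverable via a warning.
    """
    out = trials.copy()
    n = trials.n_samples
    for t, per_trial in enumerate(segments):
        for c, segs in enumerate(per_trial):
            if not segs:
                continue
            bad = np.zeros(n, dtype=bool)
            for s, e in segs:
                if not 0 <= s < e <= n:
                    raise ValueError(f"segment ({s}, {e}) out of bounds for {n} samples")
                bad[s:e] = True
            good = ~bad
            if not good.any():
                logger.warning("trial %d channel %d fully flagged: unrecoverable, zeroed", t, c)
                out.data[t, c] = 0.0
                continue
            gi = np.flatnonzero(good)
            out.data[t, c, bad] = np.interp(np.flatnonzero(bad), gi, trials.data[t, c, gi])
    return out


def reject_muscle_trials(trials: TrialSet, cfg: PreprocConfig
                         ) -> tuple[TrialSet, np.ndarray]:
    """Reject trials with high-frequency muscle activity.

    Statistic: per trial and channel, max |x| of the 120–140 Hz band-passed
    signal, z-scored across trials within each channel using the median and
    the scaled median absolute deviation.  The robust location/scale matters:
    a plain mean/SD z-score is bounded by about √n_trials and lets multiple
    strong bursts mask each other at small trial counts.  A trial is
    rejected when any channel exceeds the cutoff.
    """
    cfg.validate(trials.fs)
    lo, hi = cfg.muscle_band
    if hi >= trials.fs / 2:
        raise ValueError(f"muscle band edge {hi} Hz at or above Nyquist {trials.fs / 2}")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=trials.fs, output="sos")
    band = sps.sosfiltfilt(sos, trials.data, axis=2)
    stat = np.max(np.abs(band), axis=2)  # (n_trials, n_ch)
    med = np.median(stat, axis=0, keepdims=True)
    mad = 1.4826 * np.median(np.abs(stat - med), axis=0, keepdims=True)
    mad[mad == 0] = np.inf
    z = (stat - med) / mad
    rejected = np.flatnonzero(np.any(z > cfg.muscle_z_cutoff, axis=1))
    kept = np.setdiff1d(np.arange(trials.n_trials), rejected)
    if kept.size == 0:
        raise ValueError("all trials rejected as muscle artifacts; cannot proceed")
    return trials.select_trials(kept), rejected


# ------------------------------------------------------------- referencing


def rereference_common_average(trials: TrialSet) -> TrialSet:
    """Subtract the across-channel mean from every channel at each sample."""
    if trials.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    out = trials.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


def preprocess_trials(trials: TrialSet, cfg: PreprocConfig | None = None) -> TrialSet:
    """Full chain: filter → interpolate jumps/clips → reject muscle → re-reference."""
    cfg = cfg or PreprocConfig()
    out = filter_trials(trials, cfg)
    out = interpolate_segments(out, detect_jumps_clips(out, cfg))
    out, _ = reject_muscle_trials(out, cfg)
    return rereference_common_average(out)
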