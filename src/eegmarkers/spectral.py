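"""Frequency-domain features: trial spectra, PSDs and coherence.

Per-trial complex spectra come from a plain (untapered) FFT on the common
grid Δf = fs / n_samples; the PSD of a channel is the squared magnitude
averaged over trials.  Coherence is the magnitude of the trial-averaged,
normalized cross-spectrum, averaged per frequency band — 1 for perfectly
phase-locked channels, biased toward ~1/√n_trials for independent ones,
and identically 1 when estimated from a single trial (a degenerate case
callers should avoid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import TrialSet
from .ordinal import AdjacencyMatrix

#: band edges in Hz, inclusive on both ends
DEFAULT_BANDS = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 50.0),
}


@dataclass
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got [{self.lo}, {self.hi}]")

    @classmethod
    def named(cls, name: str) -> "BandDefinition":
        lo, hi = DEFAULT_BANDS[name]
        return cls(name, lo, hi)


@dataclass
class TrialSpectra:
    """One-sided complex spectra, shape (n_trials, n_channels, n_freqs)."""

    values: np.ndarray
    freqs: np.ndarray
    fs: float
    n_samples: int
    meta: dict = field(default_factory=dict)


@dataclass
class PSDSet:
    """Trial-averaged power spectral densities per channel.

    ``psd[c, k]`` = mean over trials of |X_c(f_k)|²; nonnegative on a
    strictly increasing frequency grid bounded by Nyquist.
    """

    psd: np.ndarray  # (n_channels, n_freqs)
    freqs: np.ndarray
    n_trials: int
    band: BandDefinition | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.psd < 0):
            raise ValueError("PSD values must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def trial_spectra(trials: TrialSet, taper: str | None = None) -> TrialSpectra:
    """One-sided DFT of every trial and channel on the common grid.

    ``taper='hann'`` applies a Hann window before the transform (off by
    default: the plain FFT is the reference behavior).
    """
    if trials.n_trials == 0:
        raise ValueError("no trials")
    x = trials.data
    if taper == "hann":
        x = x * np.hanning(trials.n_samples)[None, None, :]
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    values = np.fft.rfft(x, axis=2)
    freqs = np.fft.rfftfreq(trials.n_samples, d=1.0 / trials.fs)
    return TrialSpectra(values=values, freqs=freqs, fs=trials.fs,
                        n_samples=trials.n_samples,
                        meta={"subject": trials.subject, "group": trials.group,
                              "condition": trials.condition})


def psd_average(spectra: TrialSpectra) -> PSDSet:
    """Mean over trials of the squared spectral magnitude, per channel."""
    if spectra.values.shape[0] < 1:
        raise ValueError("need at least one trial")
    psd = np.mean(np.abs(spectra.values) ** 2, axis=0)
    return PSDSet(psd=psd, freqs=spectra.freqs.copy(),
                  n_trials=spectra.values.shape[0], meta=dict(spectra.meta))


def band_restrict(psd: PSDSet, band: BandDefinition) -> PSDSet:
    """Keep the frequency bins with lo ≤ f ≤ hi (inclusive edges)."""
    mask = (psd.freqs >= band.lo) & (psd.freqs <= band.hi)
    if not mask.any():
        raise ValueError(
            f"band [{band.lo}, {band.hi}] Hz selects no bins on a grid up to "
            f"{psd.freqs[-1]:g} Hz"
        )
    return replace(psd, psd=psd.psd[:, mask], freqs=psd.freqs[mask], band=band)


def coherence_matrix(spectra: TrialSpectra, band: BandDefinition | None = None,
                     freq_chunk: int = 64) -> AdjacencyMatrix:
    """Band-averaged magnitude coherence between all channel pairs.

    Per bin, coh_ij(f) = |⟨X_i X_j*⟩| / sqrt(⟨|X_i|²⟩⟨|X_j|²⟩) with ⟨·⟩ the
    trial mean; the matrix entry averages coh_ij(f) over the selected band's
    bins (whole grid if no band).  Diagonal is 1; values lie in [0, 1].
    """
    X = spectra.values
    n_trials, n_ch, _ = X.shape
    if n_ch < 2:
        raise ValueError("coherence needs at least 2 channels")
    freqs = spectra.freqs
    if band is not None:
        mask = (freqs >= band.lo) & (freqs <= band.hi)
        if not mask.any():
            raise ValueError(f"band [{band.lo}, {band.hi}] Hz selects no bins")
        X = X[:, :, mask]
        freqs = freqs[mask]
    power = np.mean(np.abs(X) ** 2, axis=0)  # (n_ch, n_f)
    band_power = power.sum(axis=1)
    if np.any(band_power == 0):
        dead = int(np.argmax(band_power == 0))
        raise ValueError(f"channel {dead} has zero power in the requested band")
    n_f = X.shape[2]
    acc = np.zeros((n_ch, n_ch))
    n_used = 0
    for k0 in range(0, n_f, freq_chunk):
        Xc = X[:, :, k0:k0 + freq_chunk]
        cross = np.einsum("tcf,tdf->cdf", Xc, np.conj(Xc)) / n_trials
        pw = power[:, k0:k0 + freq_chunk]
        denom = np.sqrt(pw[:, None, :] * pw[None, :, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(cross) / denom
        coh = np.nan_to_num(coh, nan=0.0)
        acc += coh.sum(axis=2)
        n_used += Xc.shape[2]
    values = acc / n_used
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    meta = dict(spectra.meta)
    meta["band"] = band.name if band else "full"
    return AdjacencyMatrix(values, kind="coherence", meta=meta)
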