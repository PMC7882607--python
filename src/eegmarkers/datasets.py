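"""In-memory containers for multichannel EEG epochs.

The atomic unit is a :class:`TrialSet` — a stack of equal-length epochs
(trials × channels × samples) from one subject under one condition, carrying
the sampling rate and channel labels.  An :class:`EEGDataset` groups the
trial sets of a whole cohort and knows each subject's group label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd


@dataclass
class TrialSet:
    """Epochs of one (subject, condition) cell.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal amplitudes in arbitrary EEG units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per channel.
    subject, group, condition : str
        Provenance labels; free-form but stable within a dataset.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"trial data must be (n_trials, n_channels, n_samples), got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but {len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "TrialSet":
        return replace(self, data=self.data.copy(), channel_names=list(self.channel_names))

    def select_trials(self, idx) -> "TrialSet":
        return replace(self, data=self.data[np.asarray(idx)])


@dataclass
class EEGDataset:
    """A cohort of trial sets keyed by (subject, condition)."""

    trialsets: dict[tuple[str, str], TrialSet] = field(default_factory=dict)

    def add(self, ts: TrialSet) -> None:
        self.trialsets[(ts.subject, ts.condition)] = ts

    def get(self, subject: str, condition: str) -> TrialSet:
        return self.trialsets[(subject, condition)]

    def __len__(self) -> int:
        return len(self.trialsets)

    def __iter__(self) -> Iterator[TrialSet]:
        return iter(self.trialsets.values())

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for subj, _ in self.trialsets:
            seen.setdefault(subj, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cond in self.trialsets:
            seen.setdefault(cond, None)
        return list(seen)

    def group_of(self, subject: str) -> str:
        for (subj, _), ts in self.trialsets.items():
            if subj == subject:
                return ts.group
        raise KeyError(subject)

    @property
    def fs(self) -> float:
        return next(iter(self.trialsets.values())).fs

    @property
    def channel_names(self) -> list[str]:
        return next(iter(self.trialsets.values())).channel_names

    def labels_frame(self) -> pd.DataFrame:
        """One row per (subject, condition) cell with its group and trial count."""
        rows = [
            {
                "subject": ts.subject,
                "group": ts.group,
                "condition": ts.condition,
                "n_trials": ts.n_trials,
            }
            for ts in self
        ]
        return pd.DataFrame(rows)

    def map_trials(self, fn) -> "EEGDataset":
        """Apply ``fn(TrialSet) -> TrialSet`` to every cell, returning a new dataset."""
        out = EEGDataset()
        for ts in self:
            out.add(fn(ts))
        return out

    # ---------------------------------------------------------------- I/O

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = self.fs
            f.attrs["channel_names"] = json.dumps(self.channel_names)
            for (subj, cond), ts in self.trialsets.items():
                g = f.create_group(f"{subj}/{cond}")
                g.create_dataset("data", data=ts.data, compression="gzip")
                g.attrs["group"] = ts.group

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EEGDataset":
        ds = cls()
        with h5py.File(path, "r") as f:
            fs = float(f.attrs["fs"])
            channels = json.loads(f.attrs["channel_names"])
            for subj in f:
                for cond in f[subj]:
                    g = f[subj][cond]
                    ds.add(
                        TrialSet(
                            data=g["data"][()],
                            fs=fs,
                            channel_names=channels,
                            subject=subj,
                            group=str(g.attrs["group"]),
                            condition=cond,
                        )
                    )
        return ds

    def to_text(self, outdir: str | Path) -> Path:
        """Write one whitespace-delimited matrix per trial plus a metadata table.

        Returns the path of the metadata TSV.  Intended for interoperability
        and small datasets; prefer HDF5 for full cohorts.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for (subj, cond), ts in self.trialsets.items():
            for t in range(ts.n_trials):
                fname = f"{subj}__{cond}__trial{t:04d}.tsv"
                np.savetxt(outdir / fname, ts.data[t], delimiter="\t")
                rows.append(
                    {
                        "subject": subj,
                        "group": ts.group,
                        "condition": cond,
                        "trial": t,
                        "file": fname,
                    }
                )
        meta = pd.DataFrame(rows)
        meta_path = outdir / "metadata.tsv"
        meta.to_csv(meta_path, sep="\t", index=False)
        with open(outdir / "recording.json", "w") as f:
            json.dump({"fs": self.fs, "channel_names": self.channel_names}, f)
        return meta_path

    @classmethod
    def from_text(cls, outdir: str | Path) -> "EEGDataset":
        outdir = Path(outdir)
        meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
        with open(outdir / "recording.json") as f:
            rec = json.load(f)
        ds = cls()
        for (subj, cond), cell in meta.groupby(["subject", "condition"], sort=False):
            cell = cell.sort_values("trial")
            data = np.stack([np.loadtxt(outdir / f, delimiter="\t") for f in cell["file"]])
            ds.add(
                TrialSet(
                    data=data,
                    fs=rec["fs"],
                    channel_names=rec["channel_names"],
                    subject=str(subj),
                    group=str(cell["group"].iloc[0]),
                    condition=str(cond),
                )
            )
        return ds


def read_edf(path: str | Path, labels: pd.DataFrame, fs_expected: float | None = None) -> EEGDataset:
    """Read continuous EDF/EDF+ recordings and epoch them by a label table.

    ``labels`` needs columns subject, group, condition, marker (sample index)
    and side ("pre" or "post"); epoch length is taken from an ``epoch_ms``
    column or defaults to 1500 ms.  Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional extra
        raise ImportError("EDF input requires the optional 'mne' dependency") from e

    from .preprocessing import epoch_continuous

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if fs_expected is not None and abs(fs - fs_expected) > 1e-9:
        raise ValueError(f"EDF sampling rate {fs} != expected {fs_expected}")
    signal = raw.get_data()
    ds = EEGDataset()
    epoch_ms = float(labels["epoch_ms"].iloc[0]) if "epoch_ms" in labels else 1500.0
    for (subj, grp, cond, side), cell in labels.groupby(
        ["subject", "group", "condition", "side"], sort=False
    ):
        ts = epoch_continuous(
            signal,
            markers=cell["marker"].to_numpy(int),
            fs=fs,
            channel_names=list(raw.ch_names),
            len_ms=epoch_ms,
            side=str(side),
        )
        ts.subject, ts.group, ts.condition = str(subj), str(grp), str(cond)
        ds.add(ts)
    return ds
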