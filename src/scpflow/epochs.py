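"""Trial-epoch containers and raw-signal I/O.

An epoch is one regulation trial: a 2 s pre-trial baseline window followed
by an 8 s trial window, single channel (FCz), in microvolts.  ``EpochSet``
holds the epochs of a whole (sub)study as dense arrays plus a metadata
frame keyed by participant / session / condition / task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import ValidationError

META_COLUMNS = ["participant", "session", "condition", "task"]


@dataclass
class Epoch:
    participant: str
    session: int
    condition: str
    task: str
    baseline: np.ndarray
    trial: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.trial = np.asarray(self.trial, dtype=float)
        if self.baseline.ndim != 1 or self.trial.ndim != 1:
            raise ValidationError("baseline and trial must be 1-D vectors")
        if not (np.isfinite(self.baseline).all() and np.isfinite(self.trial).all()):
            raise ValidationError("epoch contains non-finite samples")

    @property
    def n_trial(self) -> int:
        return self.trial.size


@dataclass
class EpochSet:
    """Dense stack of epochs sharing one sampling rate and window layout."""

    baseline: np.ndarray  # (n_epochs, n_baseline_samples)
    trial: np.ndarray     # (n_epochs, n_trial_samples)
    meta: pd.DataFrame    # one row per epoch
    sampling_rate: float

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.trial = np.asarray(self.trial, dtype=float)
        if self.baseline.shape[0] != self.trial.shape[0]:
            raise ValidationError("baseline and trial stacks disagree on epoch count")
        if len(self.meta) != self.trial.shape[0]:
            raise ValidationError("metadata rows must match epoch count")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata is missing columns {missing}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.trial.shape[0]

    def __getitem__(self, i: int) -> Epoch:
        row = self.meta.iloc[i]
        return Epoch(
            participant=row["participant"], session=int(row["session"]),
            condition=row["condition"], task=row["task"],
            baseline=self.baseline[i], trial=self.trial[i],
            sampling_rate=self.sampling_rate,
        )

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            baseline=self.baseline[mask], trial=self.trial[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
        )

    def save(self, path: str | Path) -> None:
        """Containerized array layout: one .npz with arrays + metadata columns."""
        path = Path(path)
        np.savez_compressed(
            path,
            baseline=self.baseline,
            trial=self.trial,
            sampling_rate=np.array([self.sampling_rate]),
            **{f"meta_{c}": _textsafe(self.meta[c]) for c in self.meta.columns},
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as data:
            meta = pd.DataFrame(
                {k[5:]: data[k] for k in data.files if k.startswith("meta_")}
            )
            return cls(
                baseline=data["baseline"], trial=data["trial"], meta=meta,
                sampling_rate=float(data["sampling_rate"][0]),
            )


def _textsafe(col: pd.Series) -> np.ndarray:
    arr = col.to_numpy()
    if arr.dtype == object:
        return arr.astype(np.str_)
    return arr


def read_continuous_edf(path: str | Path, channel: str = "FCz"):
    """Read one channel of a continuous EDF recording (via MNE).

    Returns ``(signal_uV, sampling_rate)``.  EDF stores volts; the signal
    is rescaled to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise ValidationError(
            f"channel {channel!r} not in EDF; available: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0] * 1e6
    return data, float(raw.info["sfreq"])


def epochs_from_continuous(signal: np.ndarray, sampling_rate: float,
                           meta: pd.DataFrame, baseline_dur: float = 2.0,
                           trial_dur: float = 8.0) -> EpochSet:
    """Cut a continuous single-channel recording into consecutive epochs.

    The recording is assumed to contain ``len(meta)`` back-to-back epochs of
    ``baseline_dur + trial_dur`` seconds each, in metadata row order.
    """
    nb = int(round(baseline_dur * sampling_rate))
    nt = int(round(trial_dur * sampling_rate))
    per = nb + nt
    needed = per * len(meta)
    if signal.size < needed:
        raise ValidationError(
            f"signal has {signal.size} samples; {needed} required for "
            f"{len(meta)} epochs of {per} samples"
        )
    chunks = signal[:needed].reshape(len(meta), per)
    return EpochSet(
        baseline=chunks[:, :nb], trial=chunks[:, nb:], meta=meta.copy(),
        sampling_rate=sampling_rate,
    )
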