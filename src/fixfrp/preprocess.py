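"""Ocular-artifact removal, fixation-locked epoching, and bandpass filtering.

The cleaning stage follows the classical ICA route: an Infomax unmixing matrix
is estimated on the 12 EEG channels of a (training) recording, components whose
activation time-course correlates strongly with any EOG channel are flagged as
ocular, and the EEG is back-projected with those components zeroed.  Epochs are
cut at fixation onsets (800 ms, i.e. round(0.8 x fs) samples — 205 at 256 Hz)
and bandpass filtered 0.5–10 Hz with a zero-phase 4th-order Butterworth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from mne.preprocessing import infomax
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

EPOCH_DURATION_S = 0.8


@dataclass
class Recording:
    """Multi-channel recording, channels x samples, microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_roles: list[str]  # "EEG" | "EOG" per channel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        if len(self.channel_roles) != len(self.channel_names):
            raise ValueError("one role per channel required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero([r == role for r in self.channel_roles])

    @property
    def eeg(self) -> np.ndarray:
        return self.data[self.indices("EEG")]

    @property
    def eog(self) -> np.ndarray:
        return self.data[self.indices("EOG")]


@dataclass
class Epoch:
    """Fixation-locked segment: channels x round(0.8 * fs) samples."""

    data: np.ndarray
    onset_sample: int
    label: str
    subject_id: str = ""
    channel_names: list[str] = field(default_factory=list)
    fs: float = 256.0


@dataclass
class ICAModel:
    unmixing: np.ndarray  # components x channels (over EEG channels)
    mixing: np.ndarray  # channels x components
    removed: set[int] = field(default_factory=set)


def epoch_length(fs: float) -> int:
    """Samples per channel in one epoch: round(0.8 * fs); 205 at 256 Hz."""
    return int(round(EPOCH_DURATION_S * fs))


def fit_ica(training: Recording, seed: int = 0) -> ICAModel:
    """Estimate a square Infomax unmixing matrix over the EEG channels.

    Requires the training stretch to be longer than 20 x n_channels^2 samples
    (a common stability heuristic) and full-rank EEG data.
    """
    eeg = training.eeg
    n_ch, n_samp = eeg.shape
    if n_samp <= 20 * n_ch**2:
        raise ValueError(
            f"training data too short for a stable ICA: need > {20 * n_ch**2} samples, "
            f"got {n_samp}"
        )
    centered = eeg - eeg.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / n_samp
    rank = np.linalg.matrix_rank(cov)
    if rank < n_ch:
        raise ValueError(f"EEG data is rank deficient (rank {rank} < {n_ch} channels)")
    # symmetric sphering before Infomax (the classical two-step estimation)
    evals, evecs = np.linalg.eigh(cov)
    sphere = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    whitened = sphere @ centered
    w = infomax(whitened.T, extended=True, rng=seed, verbose="error")
    unmixing = w @ sphere
    mixing = np.linalg.pinv(unmixing)
    return ICAModel(unmixing=unmixing, mixing=mixing)


def ica_activations(model: ICAModel, recording: Recording) -> np.ndarray:
    """Component activation time-courses: components x samples."""
    eeg = recording.eeg
    return model.unmixing @ (eeg - eeg.mean(axis=1, keepdims=True))


def select_artifact_components(
    model: ICAModel, recording: Recording, corr_threshold: float = 0.7
) -> set[int]:
    """Flag components whose activation correlates with any EOG channel at
    |r| >= corr_threshold.  Automates the manual scalp-map inspection step."""
    acts = ica_activations(model, recording)
    eog = recording.eog
    if eog.shape[0] == 0:
        raise ValueError("recording contains no EOG channels")
    flagged: set[int] = set()
    for k in range(acts.shape[0]):
        a = acts[k] - acts[k].mean()
        sa = a.std()
        if sa == 0:
            continue
        for e in eog:
            ec = e - e.mean()
            se = ec.std()
            if se == 0:
                continue
            r = float(np.dot(a, ec) / (len(a) * sa * se))
            if abs(r) >= corr_threshold:
                flagged.add(k)
                break
    return flagged


def remove_components(
    recording: Recording, model: ICAModel, indices: set[int] | list[int]
) -> Recording:
    """Back-project the EEG with the flagged components zeroed; EOG untouched."""
    indices = set(indices)
    n_comp = model.unmixing.shape[0]
    for i in indices:
        if not 0 <= i < n_comp:
            raise IndexError(f"component index {i} out of range [0, {n_comp})")
    eeg = recording.eeg
    mean = eeg.mean(axis=1, keepdims=True)
    acts = model.unmixing @ (eeg - mean)
    keep = [i for i in range(n_comp) if i not in indices]
    cleaned = model.mixing[:, keep] @ acts[keep] + mean
    data = recording.data.copy()
    data[recording.indices("EEG")] = cleaned
    return Recording(
        data=data,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        channel_roles=list(recording.channel_roles),
    )


def clean_recording(
    recording: Recording, seed: int = 0, corr_threshold: float = 0.7
) -> tuple[Recording, ICAModel]:
    """Convenience: fit ICA, flag EOG-correlated components, remove them."""
    model = fit_ica(recording, seed=seed)
    model.removed = select_artifact_components(model, recording, corr_threshold)
    return remove_components(recording, model, model.removed), model


def extract_epochs(recording: Recording, fixations, subject_id: str = "") -> list[Epoch]:
    """One epoch per fixation, starting at the fixation's first sample and
    lasting 800 ms.  Fixations whose window would run past the end of the
    recording are dropped with a logged warning."""
    n_ep = epoch_length(recording.fs)
    epochs: list[Epoch] = []
    dropped = 0
    for fx in fixations:
        onset = int(round(fx.onset_ms * recording.fs / 1000.0))
        if onset + n_ep > recording.n_samples or onset < 0:
            dropped += 1
            continue
        epochs.append(
            Epoch(
                data=recording.data[:, onset : onset + n_ep].copy(),
                onset_sample=onset,
                label=fx.label,
                subject_id=subject_id,
                channel_names=list(recording.channel_names),
                fs=recording.fs,
            )
        )
    if dropped:
        logger.warning("dropped %d fixation(s) whose epoch window exceeded the recording", dropped)
    return epochs


def _bandpass_ba(lo: float, hi: float, fs: float):
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band [{lo}, {hi}] Hz for fs = {fs} Hz")
    return butter(4, [lo, hi], btype="bandpass", fs=fs)


def bandpass_epoch(epoch: Epoch, lo: float = 0.5, hi: float = 10.0) -> Epoch:
    """Zero-phase (forward-backward) 4th-order Butterworth bandpass per channel.

    Initial conditions are chosen by Gustafsson's method, which minimizes the
    edge transients that otherwise dominate when a 0.5 Hz high-pass is applied
    to an 800 ms segment.
    """
    b, a = _bandpass_ba(lo, hi, epoch.fs)
    # remove the per-channel mean first: an 800 ms segment is shorter than the
    # 0.5 Hz high-pass time constant, so the DC component must go explicitly
    demeaned = epoch.data - epoch.data.mean(axis=1, keepdims=True)
    filtered = filtfilt(b, a, demeaned, axis=1, method="gust")
    return Epoch(
        data=filtered,
        onset_sample=epoch.onset_sample,
        label=epoch.label,
        subject_id=epoch.subject_id,
        channel_names=list(epoch.channel_names),
        fs=epoch.fs,
    )


def bandpass_epochs(epochs: list[Epoch], lo: float = 0.5, hi: float = 10.0) -> list[Epoch]:
    return [bandpass_epoch(e, lo, hi) for e in epochs]


# ---------------------------------------------------------------------------
# persistence

def write_epochs_h5(epochs: list[Epoch], path) -> None:
    arr = np.stack([e.data for e in epochs])
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=arr)
        sd = h5py.string_dtype()
        f.create_dataset("labels", data=np.array([e.label for e in epochs], dtype=sd))
        f.create_dataset("subject_ids", data=np.array([e.subject_id for e in epochs], dtype=sd))
        f.create_dataset(
            "channel_names", data=np.array(epochs[0].channel_names, dtype=sd)
        )
        f.attrs["fs"] = epochs[0].fs


def read_epochs_h5(path) -> list[Epoch]:
    with h5py.File(path, "r") as f:
        arr = f["epochs"][()]
        dec = lambda v: v.decode() if isinstance(v, bytes) else v
        labels = [dec(v) for v in f["labels"][()]]
        sids = [dec(v) for v in f["subject_ids"][()]]
        names = [dec(v) for v in f["channel_names"][()]]
        fs = float(f.attrs["fs"])
    return [
        Epoch(data=arr[i], onset_sample=-1, label=labels[i], subject_id=sids[i],
              channel_names=names, fs=fs)
        for i in range(arr.shape[0])
    ]
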