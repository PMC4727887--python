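"""Classifier-ready features: channel concatenation and PCA reduction.

Each epoch's channel-wise time courses are concatenated into one long vector
(12 EEG channels x 205 samples = 2460 dimensions in the reference setup).  PCA
then reduces dimensionality to the smallest k whose leading eigenvalues retain
a fixed fraction of the total variance (99.9 % by default).  The decomposition
is computed from the SVD of the centered data matrix, which is mathematically
identical to eigendecomposing the sample covariance but numerically stabler at
these dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Epoch

CHANNEL_SETS = ("eeg", "eog", "all")


@dataclass
class FeatureVector:
    values: np.ndarray
    label: str
    subject_id: str = ""


@dataclass
class PCAModel:
    mean: np.ndarray
    eigenvectors: np.ndarray  # d x k, columns orthonormal
    eigenvalues: np.ndarray  # descending, full spectrum (length = rank)
    k: int
    variance_fraction: float


def resolve_channel_subset(epoch: Epoch, channel_set) -> list[str]:
    """Map a preset name ('eeg' | 'eog' | 'all') or an explicit name list to
    channel names in recording order."""
    from .simulate import EEG_CHANNELS, EOG_CHANNELS

    if isinstance(channel_set, str):
        key = channel_set.lower()
        if key == "eeg":
            wanted = set(EEG_CHANNELS)
        elif key == "eog":
            wanted = set(EOG_CHANNELS)
        elif key == "all":
            wanted = set(epoch.channel_names)
        else:
            raise ValueError(f"unknown channel set {channel_set!r}")
    else:
        wanted = set(channel_set)
    unknown = wanted - set(epoch.channel_names)
    if unknown:
        raise ValueError(f"unknown channel name(s): {sorted(unknown)}")
    return [c for c in epoch.channel_names if c in wanted]


def concatenate(epoch: Epoch, channel_subset="eeg") -> FeatureVector:
    """Append the selected channels' epochs in recording channel order into one
    vector of length |subset| x epoch_samples."""
    names = resolve_channel_subset(epoch, channel_subset)
    idx = [epoch.channel_names.index(c) for c in names]
    return FeatureVector(
        values=epoch.data[idx].ravel(), label=epoch.label, subject_id=epoch.subject_id
    )


def epochs_to_matrix(epochs: list[Epoch], channel_subset="eeg"):
    """Stack concatenated epochs into (n, d) plus the label array."""
    vecs = [concatenate(e, channel_subset) for e in epochs]
    X = np.stack([v.values for v in vecs])
    y = np.array([v.label for v in vecs])
    return X, y


def fit_pca(X: np.ndarray, criterion: float = 0.999) -> PCAModel:
    """Mean-centered PCA retaining the smallest k with
    sum_{i<=k} lambda_i / sum_j lambda_j >= criterion.  Fit on training data only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 training vectors")
    if not 0 < criterion <= 1:
        raise ValueError("criterion must be in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: eigenvalues of the covariance are s^2 / (n - 1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    eigvals = eigvals[:rank]
    Vt = Vt[:rank]
    total = eigvals.sum()
    if total == 0:
        raise ValueError("data has no variance")
    frac = np.cumsum(eigvals) / total
    k = int(np.searchsorted(frac, criterion - 1e-12) + 1)
    k = min(k, rank)
    return PCAModel(
        mean=mean,
        eigenvectors=Vt[:k].T.copy(),
        eigenvalues=eigvals,
        k=k,
        variance_fraction=float(frac[k - 1]),
    )


def project(model: PCAModel, v: np.ndarray) -> np.ndarray:
    """Project (v - mean) onto the k retained eigenvectors.  Accepts a single
    vector (d,) or a matrix (n, d)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"feature length {v.shape[-1]} does not match model dimension {model.mean.shape[0]}"
        )
    return (v - model.mean) @ model.eigenvectors
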