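r"""Fisher discriminant analysis with shrinkage-regularized scatter estimation.

For classes C_j with N_j members, class means mu_j and global mean
mu = (1/n) sum_j mu_j (the unweighted average of the class means, n = number of
classes), the between-class scatter is

    S_b = sum_j N_j (mu_j - mu)(mu_j - mu)^T

and the within-class scatter is

    S_w = sum_j sum_{i in C_j} (x_i - mu_j)(x_i - mu_j)^T.

Because the training-sample count is typically small relative to the feature
dimension, the within-class covariance is replaced by the shrinkage estimate

    Sigma* = lambda * nu * I + (1 - lambda) * Sigma,   nu = trace(Sigma) / d,

i.e. a convex combination with the equal-diagonal target, with the shrinkage
intensity lambda estimated analytically (Schaefer-Strimmer plug-in).  The FDA
projection maximizes tr(P^T S_b P) / tr(P^T Sigma* P), solved as the
generalized eigenvalue problem S_b V = Lambda Sigma* V; with two classes this
reduces to the weight vector w ∝ Sigma*^{-1} (mu_+ - mu_-) and decision scores
y_i = x_i . w + b with the bias at the midpoint of the projected class means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class ClassStats:
    labels: list
    counts: np.ndarray
    means: np.ndarray  # n_classes x d
    global_mean: np.ndarray  # unweighted average of class means


@dataclass
class FDAModel:
    class_labels: list
    class_counts: np.ndarray
    class_means: np.ndarray
    global_mean: np.ndarray
    S_b: np.ndarray
    S_w: np.ndarray
    sigma_star: np.ndarray
    shrinkage: float
    projection: np.ndarray  # d x (n_classes - 1)
    eigenvalues: np.ndarray  # generalized eigenvalues, descending
    class_means_projected: np.ndarray  # n_classes x (n_classes - 1)
    w: np.ndarray | None = None  # binary case only
    b: float = 0.0

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


def scatter_matrices(X: np.ndarray, y) -> tuple[np.ndarray, np.ndarray, ClassStats]:
    """Between- and within-class scatter matrices with per-class statistics.

    The global mean is the unweighted average of the class means, so under
    class imbalance it differs from the pooled sample mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(np.unique(y).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    counts, means = [], []
    d = X.shape[1]
    S_w = np.zeros((d, d))
    for lab in labels:
        Xc = X[y == lab]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        mu_c = Xc.mean(axis=0)
        counts.append(Xc.shape[0])
        means.append(mu_c)
        R = Xc - mu_c
        S_w += R.T @ R
    counts = np.array(counts)
    means = np.stack(means)
    mu = means.mean(axis=0)
    S_b = np.zeros((d, d))
    for N_c, mu_c in zip(counts, means):
        diff = (mu_c - mu)[:, None]
        S_b += N_c * (diff @ diff.T)
    stats = ClassStats(labels=labels, counts=counts, means=means, global_mean=mu)
    return S_b, S_w, stats


def shrink_covariance(S: np.ndarray, shrinkage: float) -> np.ndarray:
    """Sigma* = lambda * nu * I + (1 - lambda) * S with nu = trace(S) / d."""
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    S = np.asarray(S, dtype=float)
    d = S.shape[0]
    nu = np.trace(S) / d
    return shrinkage * nu * np.eye(d) + (1.0 - shrinkage) * S


def estimate_shrinkage_intensity(X: np.ndarray, y) -> float:
    """Analytic plug-in estimate of the optimal shrinkage intensity toward the
    equal-diagonal target, computed on within-class centered data (pooled) and
    clipped to [0, 1].  Degenerate (zero-variance) data yields 1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Z = np.empty_like(X)
    for lab in np.unique(y):
        m = y == lab
        Z[m] = X[m] - X[m].mean(axis=0)
    n, d = Z.shape
    if n < 2:
        return 1.0
    # sample covariance and elementwise variance of its entries
    S = (Z.T @ Z) / (n - 1)
    Z2 = Z**2
    # Var(s_ij) = n / (n-1)^3 * sum_k (z_ki z_kj - mean_k)^2
    EW = (Z.T @ Z) / n  # mean of w_kij over k
    EW2 = (Z2.T @ Z2) / n  # mean of w_kij^2 over k
    var_s = n / (n - 1) ** 3 * n * (EW2 - EW**2)
    nu = np.trace(S) / d
    target = nu * np.eye(d)
    denom = float(np.sum((S - target) ** 2))
    if denom <= 0:
        return 1.0
    lam = float(np.sum(var_s)) / denom
    return float(np.clip(lam, 0.0, 1.0))


def fit_fda(X: np.ndarray, y, shrinkage: float | None = None) -> FDAModel:
    """Fit a (multi-class or binary) shrinkage-regularized Fisher discriminant.

    ``shrinkage=None`` uses the analytic estimate; an explicit value in [0, 1]
    overrides it.  With shrinkage forced to 0 on singular within-class scatter
    the fit raises, pointing at shrinkage as the remedy.
    """
    S_b, S_w, stats = scatter_matrices(X, y)
    n, d = np.asarray(X).shape
    lam = estimate_shrinkage_intensity(X, y) if shrinkage is None else float(shrinkage)
    n_classes = len(stats.labels)
    sigma_w = S_w / max(n - n_classes, 1)  # within-class covariance
    sigma_star = shrink_covariance(sigma_w, lam)
    # guard: unshrunk singular covariance cannot be inverted
    if lam == 0.0:
        if np.linalg.matrix_rank(sigma_star) < d:
            raise np.linalg.LinAlgError(
                "within-class covariance is singular with shrinkage 0; "
                "enable shrinkage (e.g. shrinkage=None for the analytic estimate)"
            )
    evals, evecs = scipy.linalg.eigh(S_b, sigma_star)
    order = np.argsort(evals)[::-1]
    n_proj = n_classes - 1
    evals = evals[order][:n_proj]
    P = evecs[:, order][:, :n_proj]
    # reproducible eigenvector sign: largest-magnitude entry positive
    for j in range(P.shape[1]):
        i = int(np.argmax(np.abs(P[:, j])))
        if P[i, j] < 0:
            P[:, j] = -P[:, j]
    means_proj = (stats.means - stats.global_mean) @ P
    model = FDAModel(
        class_labels=stats.labels,
        class_counts=stats.counts,
        class_means=stats.means,
        global_mean=stats.global_mean,
        S_b=S_b,
        S_w=S_w,
        sigma_star=sigma_star,
        shrinkage=lam,
        projection=P,
        eigenvalues=evals,
        class_means_projected=means_proj,
    )
    if n_classes == 2:
        # positive class = last label in sorted order
        mu_neg, mu_pos = stats.means
        w = np.linalg.solve(sigma_star, mu_pos - mu_neg)
        model.w = w
        model.b = float(-w @ (mu_pos + mu_neg) / 2.0)
    return model


def decision_scores(model: FDAModel, X: np.ndarray) -> np.ndarray:
    """Binary decision values y_i = x_i . w + b (positive favours the
    lexicographically larger class label)."""
    if model.w is None:
        raise ValueError("decision scores are defined for binary models only")
    X = np.asarray(X, dtype=float)
    return X @ model.w + model.b


def classify(model: FDAModel, X: np.ndarray) -> np.ndarray:
    """Binary: sign of the decision score; multi-class: nearest projected
    class mean in FDA space (Euclidean)."""
    X = np.asarray(X, dtype=float)
    if model.n_classes == 2 and model.w is not None:
        scores = decision_scores(model, X)
        neg, pos = model.class_labels
        return np.where(scores > 0, pos, neg)
    Z = (X - model.global_mean) @ model.projection
    d2 = ((Z[:, None, :] - model.class_means_projected[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray(model.class_labels, dtype=object)[idx]
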