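"""Gaussian maximum-likelihood classification of segment spectral modes.

Segments (not pixels) are the classified elements; each segment's feature
vector omega is its 4-band spectral mode.  The class-conditional density is a
multivariate Gaussian with per-class mean mu and covariance Sigma estimated by
maximum likelihood from labeled training segments; the posterior follows from
Bayes' rule with empirical or uniform priors, and a segment is assigned to the
class with the largest posterior (ties broken by declared class order).
Minimum-distance-to-means (MDM) and spectral-angle-mapper (SAM) baselines and
confusion-matrix evaluation live here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import TrainingError, ValidationError

DEFAULT_VOCABULARY: tuple[str, ...] = ("Soil", "Shadow", "HL1", "HL2", "HL3", "HL4", "HL5")
HEALTH_CLASSES: tuple[str, ...] = ("HL1", "HL2", "HL3", "HL4", "HL5")


def health_value(label: str) -> int | None:
    """Integer health level 1..5 for HL labels, None for Soil/Shadow."""
    if label in HEALTH_CLASSES:
        return int(label[2:])
    return None


@dataclass
class MlcModel:
    """Per-class Gaussian parameters and priors for maximum-likelihood classification."""

    classes: tuple[str, ...]
    means: np.ndarray  # (n_classes, dim)
    covariances: np.ndarray  # (n_classes, dim, dim)
    priors: np.ndarray  # (n_classes,)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValidationError("class priors must sum to 1")
        for c, cov in zip(self.classes, self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValidationError(f"covariance for class {c} is not symmetric")

    def to_json(self, path) -> None:
        doc = {
            "classes": list(self.classes),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "priors": self.priors.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "MlcModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            tuple(doc["classes"]),
            np.array(doc["means"]),
            np.array(doc["covariances"]),
            np.array(doc["priors"]),
        )


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Ridge near-singular covariances: eps = 1e-6 * trace / dim when the
    smallest eigenvalue falls below 1e-10 * trace."""
    d = cov.shape[0]
    tr = float(np.trace(cov))
    if tr <= 0:
        return cov + 1e-12 * np.eye(d)
    smallest = float(np.linalg.eigvalsh(cov)[0])
    if smallest < 1e-10 * tr:
        cov = cov + (1e-6 * tr / d) * np.eye(d)
    return cov


def fit_mlc(
    features: np.ndarray,
    labels,
    priors: str = "uniform",
    classes: tuple[str, ...] | None = None,
) -> MlcModel:
    """Fit per-class mean, ML (1/n) covariance and priors from labeled features.

    ``priors`` is "uniform" or "empirical".  ``classes`` fixes the class order
    (defaults to the sorted order of first appearance); a declared class with
    zero samples raises :class:`TrainingError` naming it.
    """
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    if features.ndim != 2 or len(labels) != len(features):
        raise ValidationError("features must be (n, dim) aligned with labels")
    if classes is None:
        seen: list[str] = []
        for l in labels:
            if l not in seen:
                seen.append(l)
        classes = tuple(seen)
    labels_arr = np.asarray(labels)
    means, covs, counts = [], [], []
    for c in classes:
        sel = features[labels_arr == c]
        if len(sel) == 0:
            raise TrainingError(f"class {c!r} has no training samples")
        mu = sel.mean(axis=0)
        centered = sel - mu
        cov = centered.T @ centered / len(sel)  # ML (1/n) estimate
        means.append(mu)
        covs.append(_regularize(cov))
        counts.append(len(sel))
    counts = np.asarray(counts, dtype=float)
    if priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    elif priors == "empirical":
        pri = counts / counts.sum()
    else:
        raise ValidationError("priors must be 'uniform' or 'empirical'")
    return MlcModel(classes, np.array(means), np.array(covs), pri)


def log_gaussian_density(model: MlcModel, features: np.ndarray) -> np.ndarray:
    """Log class-conditional densities, shape (n_samples, n_classes)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, d = features.shape
    out = np.empty((n, len(model.classes)))
    for j, (mu, cov) in enumerate(zip(model.means, model.covariances)):
        L = np.linalg.cholesky(cov)
        diff = features - mu
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, j] = -0.5 * maha - 0.5 * logdet - 0.5 * d * np.log(2 * np.pi)
    return out


def classify_segments(model: MlcModel, features: np.ndarray):
    """Maximum-posterior class per feature vector.

    Returns ``(labels, posteriors)`` where posteriors rows sum to 1.  Ties are
    broken by class order (argmax returns the first maximum).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.isfinite(features).all():
        raise ValidationError("feature vectors must be finite")
    log_post = log_gaussian_density(model, features) + np.log(model.priors)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    idx = np.argmax(post, axis=1)
    labels = [model.classes[i] for i in idx]
    return labels, post


def classify_baseline(method: str, means, features, classes: tuple[str, ...] | None = None):
    """Nearest-mean (mdm) or minimal spectral angle (sam) baseline labels."""
    if isinstance(means, MlcModel):
        classes = means.classes
        means = means.means
    means = np.asarray(means, dtype=float)
    if classes is None:
        classes = tuple(f"class{i}" for i in range(len(means)))
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if method == "mdm":
        d = np.linalg.norm(features[:, None, :] - means[None, :, :], axis=2)
    elif method == "sam":
        fn = np.linalg.norm(features, axis=1)
        mn = np.linalg.norm(means, axis=1)
        if (fn == 0).any() or (mn == 0).any():
            raise ValidationError("spectral angle undefined for zero-norm vectors")
        cosang = np.clip((features @ means.T) / (fn[:, None] * mn[None, :]), -1.0, 1.0)
        d = np.arccos(cosang)
    else:
        raise ValidationError(f"unknown baseline {method!r} (use 'mdm' or 'sam')")
    return [classes[i] for i in np.argmin(d, axis=1)]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Square count table: rows are ground truth, columns are predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValidationError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def precision(self, variant: str = "row_total") -> np.ndarray:
        """Per-class precision.

        ``row_total`` (default): diagonal count over its truth-row total --
        the statistic that reproduces the published per-class column.
        ``tp_tn``: TP/(TP+TN), the printed formula, kept for comparison.
        """
        diag = np.diag(self.counts).astype(float)
        if variant == "row_total":
            denom = self.counts.sum(axis=1).astype(float)
        elif variant == "tp_tn":
            total = self.counts.sum()
            tn = total - self.counts.sum(axis=1) - self.counts.sum(axis=0) + diag
            denom = diag + tn
        else:
            raise ValidationError("variant must be 'row_total' or 'tp_tn'")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, diag / denom, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["precision"] = np.round(self.precision(), 4)
        df.to_csv(path, index_label="truth")


def confusion_and_precision(truth, predicted, classes: tuple[str, ...]):
    """Count the truth-by-predicted table and per-class precision.

    Returns ``(ConfusionMatrix, precision_vector)`` with precision as
    diagonal / truth-row total, rounded to 4 decimals.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValidationError("truth and predicted must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index:
            raise ValidationError(f"truth label {t!r} outside the class list")
        if p not in index:
            raise ValidationError(f"predicted label {p!r} outside the class list")
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(tuple(classes), counts)
    return cm, np.round(cm.precision("row_total"), 4)
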