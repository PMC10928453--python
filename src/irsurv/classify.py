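"""Datapoint classification and patient scoring.

Modelling chain: mean-centred PCA to seven components, a lightly
ridge-penalised logistic regression on the component scores, per-datapoint
risk probabilities, and a patient prediction score defined as the median of
that patient's datapoint probabilities.

Uncertainty is estimated by bootstrap out-of-bag (OOB) sampling at the
**patient** level: each replicate resamples patients with replacement, fits
PCA and the classifier on the in-bag datapoints only, scores the out-of-bag
patients, and records AUROC, sensitivity and specificity on those held-out
patients.  Resampling whole patients keeps every datapoint of an OOB patient
out of the fitting set, avoiding within-patient leakage.  Medians and
half-interquartile ranges over replicates summarise the metric
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, ConvergenceError, DataError, DegenerateInputError
from .preprocess import SpectralDataset

__all__ = [
    "PCAModel",
    "LogisticModel",
    "BootstrapSummary",
    "pca_fit",
    "pca_transform",
    "logistic_fit",
    "patient_scores",
    "auroc",
    "sensitivity_specificity",
    "bootstrap_evaluate",
]


@dataclass
class PCAModel:
    """Top-k principal components of mean-centred spectra.

    ``components`` rows are the top right singular vectors (orthonormal);
    ``explained_variance`` is non-increasing.
    """

    mean_spectrum: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance: np.ndarray


@dataclass
class LogisticModel:
    """Ridge-penalised logistic regression on component scores."""

    intercept: float
    weights: np.ndarray
    ridge_penalty: float
    n_iterations: int

    def predict_proba(self, scores: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.atleast_2d(scores) @ self.weights
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


@dataclass
class BootstrapSummary:
    """Out-of-bag metric distribution over bootstrap replicates."""

    per_replicate: pd.DataFrame  # columns auroc, sensitivity, specificity
    median_auroc: float
    median_sensitivity: float
    median_specificity: float
    dispersion: dict[str, float]  # half-interquartile range per metric
    n_replicates: int
    seed: int


def pca_fit(matrix: np.ndarray, k: int = 7) -> PCAModel:
    """Top-``k`` right singular vectors of the mean-centred matrix.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive (deterministic orientation).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise DataError("expected a 2-d matrix of spectra")
    n, p = matrix.shape
    if k < 1:
        raise ConfigError("k must be at least 1")
    if n < k or p < k:
        raise DataError(f"k={k} exceeds matrix shape {matrix.shape}")
    mean = matrix.mean(axis=0)
    centred = matrix - mean
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank < k:
        raise DataError(f"k={k} exceeds achievable rank {rank}")
    components = vt[:k]
    flip = np.sign(components[np.arange(k), np.abs(components).argmax(axis=1)])
    components = components * flip[:, None]
    explained = (s[:k] ** 2) / max(n - 1, 1)
    return PCAModel(mean_spectrum=mean, components=components, explained_variance=explained)


def pca_transform(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Project (centred) rows onto the fitted components."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    return (matrix - model.mean_spectrum) @ model.components.T


def logistic_fit(
    scores: np.ndarray,
    labels: np.ndarray,
    ridge_penalty: float = 1e-4,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximise the ridge-penalised Bernoulli log-likelihood by IRLS.

    The penalty ``−½λ‖w‖²`` applies to the weights only, not the intercept.
    Convergence requires every component of the penalised gradient to fall
    below ``tol`` in magnitude.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(labels, dtype=float)
    if x.shape[0] != y.size:
        raise DataError("scores and labels must have matching lengths")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise DataError("labels must be binary 0/1")
    if classes.size < 2:
        raise DataError("both classes must be present to fit the classifier")
    if ridge_penalty < 0:
        raise ConfigError("ridge_penalty must be non-negative")

    design = np.column_stack([np.ones(x.shape[0]), x])
    penalty = np.full(design.shape[1], ridge_penalty)
    penalty[0] = 0.0  # intercept unpenalised
    beta = np.zeros(design.shape[1])
    for iteration in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        gradient = design.T @ (y - mu) - penalty * beta
        if np.max(np.abs(gradient)) < tol:
            return LogisticModel(
                intercept=float(beta[0]),
                weights=beta[1:].copy(),
                ridge_penalty=ridge_penalty,
                n_iterations=iteration - 1,
            )
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hessian = (design * w[:, None]).T @ design + np.diag(penalty)
        beta = beta + np.linalg.solve(hessian, gradient)
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(max |gradient| = {np.max(np.abs(gradient)):.3e})"
    )


def patient_scores(probabilities: np.ndarray, meta: pd.DataFrame) -> pd.Series:
    """Median datapoint probability per patient (midpoint rule at even counts)."""
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    if probabilities.size != len(meta):
        raise DataError("one probability per datapoint required")
    frame = pd.DataFrame(
        {"patient_id": meta["patient_id"].astype(str).to_numpy(), "p": probabilities}
    )
    scores = frame.groupby("patient_id", sort=True)["p"].median()
    scores.name = "score"
    return scores


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a positive outranks a negative, ties counted half.

    Equivalent to (concordant + ½·tied) / (positives × negatives), computed
    via midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUROC undefined with a single class")
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float]:
    """True-positive and true-negative rates calling ``score >= threshold``
    positive (positives = high risk)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    predicted = scores >= threshold
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("sensitivity/specificity undefined with one class")
    sensitivity = float((predicted & (labels == 1)).sum() / n_pos)
    specificity = float((~predicted & (labels == 0)).sum() / n_neg)
    return sensitivity, specificity


def _fit_and_score(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    test_matrix: np.ndarray,
    n_components: int,
    ridge_penalty: float,
) -> np.ndarray:
    pca = pca_fit(train_matrix, k=n_components)
    model = logistic_fit(
        pca_transform(pca, train_matrix), train_labels, ridge_penalty=ridge_penalty
    )
    return model.predict_proba(pca_transform(pca, test_matrix))


def bootstrap_evaluate(
    dataset: SpectralDataset,
    labels: pd.Series,
    n_replicates: int = 500,
    seed: int = 0,
    n_components: int = 7,
    ridge_penalty: float = 1e-4,
    threshold: float = 0.5,
    max_attempts_factor: int = 50,
) -> tuple[BootstrapSummary, pd.Series]:
    """Patient-level bootstrap OOB evaluation plus full-data patient scores.

    ``labels`` maps patient_id → 0/1 (patients absent from it, e.g. excluded
    by the survival endpoint, are ignored for fitting and metrics).  Each
    replicate draws patients with replacement; in-bag datapoints (with
    multiplicity) fit PCA then the classifier; OOB patients are scored by
    their median datapoint probability.  Replicates whose OOB set is empty or
    single-class are discarded and redrawn.  The returned series holds
    full-data-model scores for **all** patients in the dataset, labelled or
    not.
    """
    if n_replicates < 10:
        raise ConfigError("need at least 10 bootstrap replicates")
    labels = labels.astype(int)
    labels.index = labels.index.astype(str)
    patients = np.array([p for p in dataset.patients() if p in labels.index])
    if patients.size < 2:
        raise DegenerateInputError("need at least two labelled patients")
    y_patient = labels.loc[patients]
    if y_patient.nunique() < 2 or y_patient.value_counts().min() < 2:
        raise DegenerateInputError("need at least two labelled patients per class")

    patient_ids = dataset.meta["patient_id"].astype(str).to_numpy()
    row_index = {p: np.flatnonzero(patient_ids == p) for p in patients}

    rng = np.random.default_rng(seed)
    records = []
    attempts = 0
    max_attempts = max_attempts_factor * n_replicates
    while len(records) < n_replicates:
        attempts += 1
        if attempts > max_attempts:
            raise ConvergenceError(
                f"could not collect {n_replicates} two-class OOB replicates "
                f"in {max_attempts} draws"
            )
        drawn = rng.choice(patients, size=patients.size, replace=True)
        oob = np.setdiff1d(patients, drawn)
        if oob.size == 0 or labels.loc[oob].nunique() < 2:
            continue
        if labels.loc[np.unique(drawn)].nunique() < 2:
            continue  # single-class in-bag: classifier unfittable, redraw
        train_rows = np.concatenate([row_index[p] for p in drawn])
        oob_rows = np.concatenate([row_index[p] for p in oob])
        probabilities = _fit_and_score(
            dataset.matrix[train_rows],
            labels.loc[patient_ids[train_rows]].to_numpy(),
            dataset.matrix[oob_rows],
            n_components,
            ridge_penalty,
        )
        scores = patient_scores(probabilities, dataset.meta.iloc[oob_rows])
        y_oob = labels.loc[scores.index].to_numpy()
        sens, spec = sensitivity_specificity(scores.to_numpy(), y_oob, threshold)
        records.append(
            {
                "auroc": auroc(scores.to_numpy(), y_oob),
                "sensitivity": sens,
                "specificity": spec,
            }
        )

    per_replicate = pd.DataFrame(records)
    q1 = per_replicate.quantile(0.25)
    q3 = per_replicate.quantile(0.75)
    summary = BootstrapSummary(
        per_replicate=per_replicate,
        median_auroc=float(per_replicate["auroc"].median()),
        median_sensitivity=float(per_replicate["sensitivity"].median()),
        median_specificity=float(per_replicate["specificity"].median()),
        dispersion={m: float((q3[m] - q1[m]) / 2.0) for m in per_replicate.columns},
        n_replicates=n_replicates,
        seed=seed,
    )

    labelled_rows = np.concatenate([row_index[p] for p in patients])
    final_probabilities = _fit_and_score(
        dataset.matrix[labelled_rows],
        labels.loc[patient_ids[labelled_rows]].to_numpy(),
        dataset.matrix,
        n_components,
        ridge_penalty,
    )
    return summary, patient_scores(final_probabilities, dataset.meta)
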