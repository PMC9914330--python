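"""Canonical discriminant analysis, stepwise selection and cross-validation.

This is the origin-authentication engine: given labelled fatty-acid vectors
(here, three cod groups of 15 fish), it finds the linear combinations of
fatty acids — canonical roots — that maximize between-group relative to
within-group variance, selects which acids to use via Wilks'-lambda forward
stepwise testing, classifies samples with the pooled-covariance linear rule,
and estimates honest accuracy by leave-one-out cross-validation.

Model
-----
With total scatter T, pooled within-group scatter W and between-group
scatter B = T − W, the canonical roots are the eigenvectors of W⁻¹B. The
eigenproblem is solved in symmetrized form (Cholesky W = LLᵀ, then a
symmetric eigensolver on L⁻¹BL⁻ᵀ) for numerical stability. With g groups
and p variables there are min(g − 1, p) roots; each eigenvalue λᵢ maps to a
canonical correlation ρᵢ = √(λᵢ/(1 + λᵢ)). Raw coefficients are scaled so
the canonical variates have unit pooled within-class variance, and
standardized coefficients multiply the raw ones by each variable's pooled
within-class SD (total-sample standardization can be selected instead).
Root signs are fixed by orienting each axis so its largest-magnitude
standardized coefficient is positive.

Stepwise entry test: with p variables already entered, a candidate's
partial F is ((1 − Λr)/Λr)·((n − g − p)/(g − 1)) where Λr is the ratio of
the augmented to the current Wilks' Λ; the candidate minimizing Λ enters
iff its partial F has p-value ≤ ``slentry``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "CanonicalModel",
    "ConfusionMatrix",
    "SingularMatrixError",
    "scatter_matrices",
    "wilks_lambda",
    "stepwise_select",
    "fit_cda",
    "classify",
    "classify_batch",
    "loo_crossvalidate",
    "resubstitution",
    "plot_scores",
]

#: Eigenvalues below RANK_TOL × λ₁ are treated as zero.
RANK_TOL = 1e-10


class SingularMatrixError(np.linalg.LinAlgError):
    """The pooled within-group scatter is singular (collinear variables)."""


def _as_matrix(
    X, variables: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if variables is not None:
            missing = [v for v in variables if v not in X.columns]
            if missing:
                raise KeyError(f"variables not in data: {missing}")
            X = X[list(variables)]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D samples × variables matrix")
    names = list(variables) if variables is not None else [
        f"x{j}" for j in range(arr.shape[1])
    ]
    if len(names) != arr.shape[1]:
        raise ValueError("variables length does not match X")
    return arr, names


def _check_groups(labels: np.ndarray) -> list[str]:
    # first-appearance order keeps group handling deterministic
    order = list(dict.fromkeys(labels.tolist()))
    counts = {g: int((labels == g).sum()) for g in order}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"singleton group(s): {small}; each group needs >= 2 samples")
    return order


def _collinear_names(within_centered: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = linalg.qr(within_centered, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0:
        return list(names)
    rank = int((diag > diag[0] * 1e-9).sum())
    return [names[j] for j in sorted(piv[rank:])]


def scatter_matrices(
    X, labels, variables: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total, pooled within-group and between-group scatter (T, W, B).

    T is the centered cross-product of all samples, W sums each group's
    centered cross-product, and B = T − W; the decomposition T = W + B is
    exact. Raises :class:`SingularMatrixError`, naming the collinear
    variables, if W is rank-deficient.
    """
    data, names = _as_matrix(X, variables)
    lab = np.asarray(labels)
    if lab.shape[0] != data.shape[0]:
        raise ValueError("labels length does not match X")
    groups = _check_groups(lab)

    centered_total = data - data.mean(axis=0)
    T = centered_total.T @ centered_total
    within_rows = np.empty_like(data)
    for g in groups:
        mask = lab == g
        within_rows[mask] = data[mask] - data[mask].mean(axis=0)
    W = within_rows.T @ within_rows
    B = T - W

    if len(groups) > 1:
        sign, logdet = np.linalg.slogdet(W)
        if sign <= 0 or not np.isfinite(logdet):
            bad = _collinear_names(within_rows, names)
            raise SingularMatrixError(
                "pooled within-group scatter is singular; collinear "
                f"variable(s): {bad}"
            )
    return T, W, B


def wilks_lambda(X, labels, variables: Sequence[str] | None = None) -> float:
    """Wilks' Λ = det(W)/det(T) for the given variable set (1 if empty)."""
    data, names = _as_matrix(X, variables)
    if data.shape[1] == 0:
        return 1.0
    T, W, _ = scatter_matrices(data, labels, names)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0:
        raise SingularMatrixError("total scatter is singular")
    return float(np.exp(logdet_w - logdet_t))


def stepwise_select(
    X,
    labels,
    slentry: float = 0.05,
    variables: Sequence[str] | None = None,
) -> list[str]:
    """Forward stepwise variable selection on Wilks' Λ.

    At each step the candidate that minimizes the Λ of the augmented set is
    admitted iff its partial-F p-value is ≤ ``slentry``; ties break by
    candidate order. Returns the entered variables in entry order (possibly
    empty).
    """
    data, names = _as_matrix(X, variables)
    lab = np.asarray(labels)
    groups = _check_groups(lab)
    g = len(groups)
    n = data.shape[0]

    selected: list[int] = []
    remaining = list(range(len(names)))
    current_lambda = 1.0
    while remaining and (n - g - len(selected)) > 0:
        best: tuple[float, int] | None = None
        for j in remaining:
            cols = selected + [j]
            try:
                lam = wilks_lambda(data[:, cols], lab, [names[c] for c in cols])
            except SingularMatrixError:
                continue
            if best is None or lam < best[0]:
                best = (lam, j)
        if best is None:
            break
        lam, j = best
        ratio = lam / current_lambda
        p_in = len(selected)
        df2 = n - g - p_in
        if ratio <= 0:
            p_value = 0.0
        else:
            f_stat = ((1.0 - ratio) / ratio) * (df2 / (g - 1))
            p_value = float(stats.f.sf(f_stat, g - 1, df2))
        if p_value > slentry:
            break
        selected.append(j)
        remaining.remove(j)
        current_lambda = lam
    return [names[j] for j in selected]


@dataclass
class CanonicalModel:
    """A fitted canonical discriminant space plus the linear classifier."""

    variables: list[str]
    groups: list[str]
    eigenvalues: np.ndarray
    canonical_correlations: np.ndarray
    cumulative_proportion: np.ndarray
    raw_coefficients: pd.DataFrame          # variables × roots
    standardized_coefficients: pd.DataFrame  # variables × roots
    group_centroids: pd.DataFrame           # groups × roots (canonical space)
    group_means: pd.DataFrame               # groups × variables (original space)
    overall_mean: pd.Series
    pooled_within_cov: pd.DataFrame         # p × p, W/(n − g)
    priors: dict[str, float]

    @property
    def n_roots(self) -> int:
        return int(self.eigenvalues.size)

    def transform(self, X) -> np.ndarray:
        """Project samples onto the canonical roots."""
        data, _ = _as_matrix(X, self.variables)
        return (data - self.overall_mean.to_numpy()) @ self.raw_coefficients.to_numpy()

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "groups": self.groups,
            "eigenvalues": self.eigenvalues.tolist(),
            "canonical_correlations": self.canonical_correlations.tolist(),
            "cumulative_proportion": self.cumulative_proportion.tolist(),
            "raw_coefficients": self.raw_coefficients.to_dict(orient="index"),
            "standardized_coefficients": self.standardized_coefficients.to_dict(
                orient="index"
            ),
            "group_centroids": self.group_centroids.to_dict(orient="index"),
            "group_means": self.group_means.to_dict(orient="index"),
            "overall_mean": self.overall_mean.to_dict(),
            "pooled_within_cov": self.pooled_within_cov.to_dict(orient="index"),
            "priors": self.priors,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_cda(
    X,
    labels,
    variables: Sequence[str] | None = None,
    priors: Mapping[str, float] | None = None,
    standardize: str = "pooled",
) -> CanonicalModel:
    """Fit the canonical discriminant model.

    ``standardize`` chooses the SDs used for standardized coefficients:
    ``"pooled"`` (within-class, the convention of the classical procedure)
    or ``"total"``. Requires p ≤ n − g so the pooled scatter is full rank.
    """
    data, names = _as_matrix(X, variables)
    lab = np.asarray(labels)
    groups = _check_groups(lab)
    n, p = data.shape
    g = len(groups)
    if p > n - g:
        raise ValueError(
            f"{p} variables with only {n} samples in {g} groups: need p <= n - g"
        )
    if standardize not in ("pooled", "total"):
        raise ValueError("standardize must be 'pooled' or 'total'")

    T, W, B = scatter_matrices(data, lab, names)
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as err:  # pragma: no cover - guarded above
        raise SingularMatrixError(str(err)) from err
    Linv = linalg.solve_triangular(L, np.eye(p), lower=True)
    M = Linv @ B @ Linv.T
    eigvals, eigvecs = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    n_roots = min(g - 1, p)
    eigvals = np.clip(eigvals[:n_roots], 0.0, None)
    if eigvals.size and eigvals[0] > 0:
        eigvals[eigvals < RANK_TOL * eigvals[0]] = 0.0
    vecs = eigvecs[:, :n_roots]

    # A'WA = I; scale by sqrt(n - g) for unit pooled within-class *variance*
    A = Linv.T @ vecs * np.sqrt(n - g)

    pooled_cov = W / (n - g)
    if standardize == "pooled":
        sds = np.sqrt(np.diag(pooled_cov))
    else:
        sds = np.sqrt(np.diag(T) / (n - 1))
    std_coef = A * sds[:, None]

    # orient each root so its largest-|standardized coefficient| is positive
    for r in range(std_coef.shape[1]):
        lead = np.argmax(np.abs(std_coef[:, r]))
        if std_coef[lead, r] < 0:
            std_coef[:, r] *= -1.0
            A[:, r] *= -1.0

    total = eigvals.sum()
    cumulative = (
        np.cumsum(eigvals) / total if total > 0 else np.zeros_like(eigvals)
    )
    rho = np.sqrt(eigvals / (1.0 + eigvals))

    overall_mean = data.mean(axis=0)
    means = np.vstack([data[lab == grp].mean(axis=0) for grp in groups])
    centroids = (means - overall_mean) @ A

    if priors is None:
        prior_map = {grp: 1.0 / g for grp in groups}
    else:
        total_prior = float(sum(priors[grp] for grp in groups))
        prior_map = {grp: float(priors[grp]) / total_prior for grp in groups}

    roots = [f"root{r + 1}" for r in range(n_roots)]
    return CanonicalModel(
        variables=names,
        groups=groups,
        eigenvalues=eigvals,
        canonical_correlations=rho,
        cumulative_proportion=cumulative,
        raw_coefficients=pd.DataFrame(A, index=names, columns=roots),
        standardized_coefficients=pd.DataFrame(std_coef, index=names, columns=roots),
        group_centroids=pd.DataFrame(centroids, index=groups, columns=roots),
        group_means=pd.DataFrame(means, index=groups, columns=names),
        overall_mean=pd.Series(overall_mean, index=names),
        pooled_within_cov=pd.DataFrame(pooled_cov, index=names, columns=names),
        priors=prior_map,
    )


def _linear_scores(
    x: np.ndarray,
    means: np.ndarray,
    pooled_cov: np.ndarray,
    log_priors: np.ndarray,
) -> np.ndarray:
    """Log-posterior-proportional linear discriminant scores per group."""
    solve = np.linalg.solve(pooled_cov, means.T)  # p × g
    const = -0.5 * np.einsum("jg,jg->g", means.T, solve) + log_priors
    return x @ solve + const


def classify(
    model: CanonicalModel, x: Mapping[str, float] | Sequence[float]
) -> tuple[str, dict[str, float]]:
    """Classify one sample; returns (predicted group, posterior per group).

    Uses the pooled-covariance linear rule with the model's priors;
    posteriors sum to 1 and ties break by group order.
    """
    if isinstance(x, Mapping):
        missing = [v for v in model.variables if v not in x]
        if missing:
            raise KeyError(f"sample is missing model variable(s): {missing}")
        vec = np.array([float(x[v]) for v in model.variables])
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (len(model.variables),):
            raise ValueError(
                f"expected {len(model.variables)} values, got shape {vec.shape}"
            )
    scores = _linear_scores(
        vec[None, :],
        model.group_means.to_numpy(),
        model.pooled_within_cov.to_numpy(),
        np.log([model.priors[g] for g in model.groups]),
    )[0]
    shifted = scores - scores.max()
    post = np.exp(shifted)
    post /= post.sum()
    winner = model.groups[int(np.argmax(post))]
    return winner, dict(zip(model.groups, post.tolist()))


def classify_batch(model: CanonicalModel, X) -> list[str]:
    data, _ = _as_matrix(X, model.variables)
    scores = _linear_scores(
        data,
        model.group_means.to_numpy(),
        model.pooled_within_cov.to_numpy(),
        np.log([model.priors[g] for g in model.groups]),
    )
    return [model.groups[j] for j in np.argmax(scores, axis=1)]


@dataclass
class ConfusionMatrix:
    """Observed × predicted counts with overall and per-group accuracy."""

    labels: list[str]
    counts: pd.DataFrame  # rows: observed, columns: predicted

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        """Overall % correctly classified (100 × trace / total)."""
        return 100.0 * float(np.trace(self.counts.to_numpy())) / self.total

    def per_group_accuracy(self) -> pd.Series:
        mat = self.counts.to_numpy()
        return pd.Series(
            100.0 * np.diag(mat) / mat.sum(axis=1), index=self.labels,
            name="correct_%",
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc["correct_%"] = self.per_group_accuracy().reindex(out.columns)
        out.to_csv(path, index_label="observed\\predicted")


def _confusion(
    observed: Sequence[str], predicted: Sequence[str], groups: list[str]
) -> ConfusionMatrix:
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for obs, pred in zip(observed, predicted):
        counts.loc[obs, pred] += 1
    return ConfusionMatrix(labels=groups, counts=counts)


def resubstitution(
    X, labels, variables: Sequence[str] | None = None,
    priors: Mapping[str, float] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix when the training samples classify themselves."""
    data, names = _as_matrix(X, variables)
    lab = np.asarray(labels)
    model = fit_cda(data, lab, names, priors=priors)
    return _confusion(lab.tolist(), classify_batch(model, data), model.groups)


def loo_crossvalidate(
    X, labels, variables: Sequence[str] | None = None,
    priors: Mapping[str, float] | None = None,
) -> ConfusionMatrix:
    """Leave-one-out cross-validated confusion matrix.

    The variable set is held fixed; for each held-out sample the classifier
    (group means and pooled covariance) is refit on the other n − 1 samples
    and the held-out sample predicted. Every group needs ≥ 3 samples so each
    fold retains ≥ 2 per group.
    """
    data, names = _as_matrix(X, variables)
    lab = np.asarray(labels)
    groups = _check_groups(lab)
    counts = {g: int((lab == g).sum()) for g in groups}
    small = [g for g, c in counts.items() if c < 3]
    if small:
        raise ValueError(
            f"leave-one-out needs >= 3 samples per group; too small: {small}"
        )
    g = len(groups)
    if priors is None:
        prior_map = {grp: 1.0 / g for grp in groups}
    else:
        total_prior = float(sum(priors[grp] for grp in groups))
        prior_map = {grp: float(priors[grp]) / total_prior for grp in groups}
    log_priors = np.log([prior_map[grp] for grp in groups])

    n = data.shape[0]
    predictions: list[str] = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train, train_lab = data[keep], lab[keep]
        means = np.vstack([train[train_lab == grp].mean(axis=0) for grp in groups])
        within = np.vstack(
            [
                train[train_lab == grp] - train[train_lab == grp].mean(axis=0)
                for grp in groups
            ]
        )
        pooled = (within.T @ within) / (train.shape[0] - g)
        sign, logdet = np.linalg.slogdet(pooled)
        if sign <= 0 or not np.isfinite(logdet):
            raise SingularMatrixError(
                f"fold {i}: pooled within-group covariance is singular"
            )
        scores = _linear_scores(data[i][None, :], means, pooled, log_priors)[0]
        predictions.append(groups[int(np.argmax(scores))])
    return _confusion(lab.tolist(), predictions, groups)


def plot_scores(
    model: CanonicalModel, X, labels, path: str | Path, title: str | None = None
) -> None:
    """Scatter of samples on the first two canonical roots (or a strip
    chart when the model has a single root), with group centroids marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = model.transform(X)
    lab = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = ["o", "s", "^", "D", "v"]
    for k, grp in enumerate(model.groups):
        mask = lab == grp
        if model.n_roots >= 2:
            ax.scatter(
                scores[mask, 0], scores[mask, 1],
                marker=markers[k % len(markers)], label=grp, alpha=0.8,
            )
        else:
            jitter = (np.arange(mask.sum()) - mask.sum() / 2) * 0.02
            ax.scatter(
                scores[mask, 0], np.full(mask.sum(), k) + jitter,
                marker=markers[k % len(markers)], label=grp, alpha=0.8,
            )
    if model.n_roots >= 2:
        cent = model.group_centroids.to_numpy()
        ax.scatter(
            cent[:, 0], cent[:, 1], marker="x", s=90, c="black", label="centroids"
        )
        ax.set_xlabel("root 1")
        ax.set_ylabel("root 2")
    else:
        ax.set_xlabel("root 1")
        ax.set_yticks(range(len(model.groups)), model.groups)
    ax.axhline(0, lw=0.5, c="grey")
    ax.axvline(0, lw=0.5, c="grey")
    ax.legend()
    ax.set_title(title or "Canonical discriminant scores")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
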