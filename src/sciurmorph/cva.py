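"""Canonical variates analysis of Procrustes coordinates and classification.

Groups (dietary or locomotor categories) are compared in the shape tangent
space. Because Procrustes data are rank-deficient, the data are first
reduced to the PCA subspace holding all non-null variance, capped at N - g
dimensions so the pooled within-group covariance is invertible. Canonical
axes solve the between/within generalized eigenproblem, scaled so canonical
scores have unit pooled within-group variance. Specimens (including ones
left out of the fit, such as a fossil of unknown ecology) are assigned to
the group of smallest Mahalanobis distance, with equal-prior Gaussian
posteriors; accuracy is reported both by resubstitution and by
leave-one-out cross-validation that refits the whole CVA per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .datatypes import ShapeDataset
from .superimposition import procrustes_distance

GroupingSpec = Union[str, Sequence[str]]


def resolve_grouping(dataset: ShapeDataset, grouping: GroupingSpec) -> np.ndarray:
    """Per-specimen group labels; 'ungrouped' marks exclusion from fits."""
    if isinstance(grouping, str):
        if grouping == "diet":
            return np.array(dataset.diets)
        if grouping == "locomotion":
            return np.array(dataset.locomotions)
        raise ValueError(f"unknown grouping {grouping!r}; use 'diet', 'locomotion',"
                         " or a per-specimen label sequence")
    labels = np.asarray(list(grouping), dtype=object)
    if labels.size != dataset.n:
        raise ValueError("grouping sequence must match specimen count")
    return labels


@dataclass
class CVAModel:
    groups: list[str]
    canonical_axes: np.ndarray  # (m, 2k) in landmark space, for wireframes
    axes_reduced: np.ndarray  # (m, r) in the PCA subspace
    eigenvalues: np.ndarray  # (m,)
    percent_variance: np.ndarray  # (m,)
    group_means_reduced: np.ndarray  # (g, r)
    group_means_canonical: np.ndarray  # (g, m)
    winv: np.ndarray  # (r, r) pooled within-group precision
    within: np.ndarray  # (r, r) pooled within-group covariance
    reduction_basis: np.ndarray  # (r, 2k)
    center: np.ndarray  # (2k,)
    subspace_dim: int
    excluded_groups: list[str] = field(default_factory=list)

    def reduce(self, Y: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(Y) - self.center) @ self.reduction_basis.T

    def canonical_scores(self, Y: np.ndarray) -> np.ndarray:
        return self.reduce(Y) @ self.axes_reduced.T

    def shape_at_score(self, axis: int, score: float) -> np.ndarray:
        """Reconstructed k x 2 shape at a canonical score (1-based axis).

        The displayed displacement per unit canonical score is the
        within-covariance image of the canonical eigenvector (the expected
        shape change accompanying a unit score change), mapped back to
        landmark space.
        """
        if not 1 <= axis <= self.axes_reduced.shape[0]:
            raise ValueError(f"axis {axis} out of range")
        v = self.axes_reduced[axis - 1]
        disp = (self.within @ v) @ self.reduction_basis
        vec = self.center + score * disp
        return vec.reshape(-1, 2)

    def mahalanobis_sq(self, Y: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row to each group mean, (n, g)."""
        Z = self.reduce(Y)
        out = np.empty((Z.shape[0], len(self.groups)))
        for j, mu in enumerate(self.group_means_reduced):
            d = Z - mu
            out[:, j] = np.einsum("ij,jk,ik->i", d, self.winv, d)
        return out


def fit_cva(
    dataset: ShapeDataset,
    grouping: GroupingSpec = "diet",
    subspace_cap: Optional[int] = None,
) -> CVAModel:
    """Fit a CVA on the grouped specimens of an aligned dataset.

    Ungrouped specimens never enter the fit; groups of size 1 are excluded
    with a warning. ``subspace_cap`` overrides the default N - g dimension
    cap of the PCA reduction.
    """
    Y = dataset.require_aligned()
    labels = resolve_grouping(dataset, grouping)

    counts = pd.Series(labels).value_counts()
    groups = sorted(g for g in counts.index if g != "ungrouped" and counts[g] >= 2)
    excluded = sorted(g for g in counts.index if g != "ungrouped" and counts[g] < 2)
    for g in excluded:
        warnings.warn(f"group {g!r} has a single specimen; excluded from CVA",
                      RuntimeWarning)
    if len(groups) < 2:
        raise ValueError("CVA needs at least 2 groups with >= 2 specimens")
    mask = np.isin(labels, groups)
    Yg, lg = Y[mask], labels[mask]
    N, g = Yg.shape[0], len(groups)

    center = Yg.mean(axis=0)
    Yc = Yg - center
    # PCA reduction for invertibility: non-null variance, capped at N - g
    cov = (Yc.T @ Yc) / (N - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cap = subspace_cap if subspace_cap is not None else N - g
    keep = evals > 1e-12 * max(evals.sum(), 1e-300)
    r = min(int(keep.sum()), cap)
    if r < 1:
        raise ValueError(
            f"no usable subspace: N={N}, g={g}, non-null dims={int(keep.sum())}"
        )
    P = evecs[:, :r].T  # (r, 2k)
    Z = Yc @ P.T

    mu = Z.mean(axis=0)
    B = np.zeros((r, r))
    W = np.zeros((r, r))
    means = np.empty((g, r))
    for j, grp in enumerate(groups):
        m = lg == grp
        zj = Z[m]
        means[j] = zj.mean(axis=0)
        dj = means[j] - mu
        B += m.sum() * np.outer(dj, dj)
        W += (zj - means[j]).T @ (zj - means[j])
    B /= g - 1
    W /= N - g
    try:
        cvals, cvecs = eigh(B, W)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular within-group covariance in {r}-dim subspace "
            f"(N={N}, g={g}); reduce subspace_cap"
        ) from exc
    order = np.argsort(cvals)[::-1]
    m_axes = min(g - 1, r)
    cvals = np.clip(cvals[order][:m_axes], 0, None)
    axes = cvecs[:, order][:, :m_axes].T  # rows; v' W v = 1 scaling from eigh

    # deterministic sign: largest-|entry| of the landmark-space axis positive
    axes_full = axes @ P
    for i in range(axes_full.shape[0]):
        j = np.argmax(np.abs(axes_full[i]))
        if axes_full[i, j] < 0:
            axes_full[i] = -axes_full[i]
            axes[i] = -axes[i]

    total = cvals.sum()
    percent = 100.0 * cvals / total if total > 0 else np.zeros_like(cvals)
    return CVAModel(
        groups=groups,
        canonical_axes=axes_full,
        axes_reduced=axes,
        eigenvalues=cvals,
        percent_variance=percent,
        group_means_reduced=means,
        group_means_canonical=(means - mu) @ axes.T,
        winv=np.linalg.inv(W),
        within=W,
        reduction_basis=P,
        center=center,
        subspace_dim=r,
        excluded_groups=excluded,
    )


@dataclass
class ClassificationTable:
    table: pd.DataFrame  # per-specimen rows
    confusion: pd.DataFrame  # percent rows by true group (resubstitution)
    confusion_cv: Optional[pd.DataFrame]
    percent_correct: float
    percent_correct_cv: Optional[float]


def _assign(model: CVAModel, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = model.mahalanobis_sq(Y)
    # equal priors; subtract the row minimum before exponentiating for stability
    w = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / 2.0)
    post = w / w.sum(axis=1, keepdims=True)
    pred = d2.argmin(axis=1)  # argmin takes the lowest index on exact ties
    return pred, post


def classify_specimens(
    model: CVAModel,
    dataset: ShapeDataset,
    grouping: GroupingSpec = "diet",
    cross_validate: bool = False,
) -> ClassificationTable:
    """Assign every specimen to its nearest group (Mahalanobis, equal priors).

    Ungrouped specimens are classified without having entered the fit. With
    ``cross_validate``, each grouped specimen is classified by a CVA refitted
    without it (leave-one-out); folds that would empty a group are skipped
    with a warning.
    """
    Y = dataset.require_aligned()
    labels = resolve_grouping(dataset, grouping)
    pred_idx, post = _assign(model, Y)
    pred = np.array([model.groups[i] for i in pred_idx], dtype=object)

    cv_pred = np.array([None] * dataset.n, dtype=object)
    if cross_validate:
        label_counts = pd.Series(labels).value_counts()
        for i in range(dataset.n):
            if labels[i] not in model.groups:
                continue
            if label_counts[labels[i]] <= 2:
                warnings.warn(
                    f"leave-one-out fold for specimen {dataset.specimen_ids[i]!r} "
                    f"would leave group {labels[i]!r} too small; fold skipped",
                    RuntimeWarning,
                )
                continue
            keep = np.ones(dataset.n, dtype=bool)
            keep[i] = False
            sub = ShapeDataset(
                specimens=[dataset.specimens[j] for j in range(dataset.n) if keep[j]],
                consensus=dataset.consensus,
                tangent_coords=Y[keep],
                gpa_converged=dataset.gpa_converged,
            )
            sub_model = fit_cva(sub, labels[keep])
            p_i, _ = _assign(sub_model, Y[i : i + 1])
            cv_pred[i] = sub_model.groups[p_i[0]]

    rows = pd.DataFrame(
        {
            "specimen_id": dataset.specimen_ids,
            "taxon": dataset.taxa,
            "true_group": labels,
            "predicted": pred,
            "cv_predicted": cv_pred,
        }
    )
    for j, grp in enumerate(model.groups):
        rows[f"p_{grp}"] = post[:, j]

    fitted = rows["true_group"].isin(model.groups)
    confusion = _confusion(rows[fitted], "predicted", model.groups)
    pct = float(
        100.0 * (rows.loc[fitted, "predicted"] == rows.loc[fitted, "true_group"]).mean()
    )
    confusion_cv = None
    pct_cv = None
    if cross_validate:
        cv_rows = rows[fitted & rows["cv_predicted"].notna()]
        if len(cv_rows):
            confusion_cv = _confusion(cv_rows, "cv_predicted", model.groups)
            pct_cv = float(
                100.0 * (cv_rows["cv_predicted"] == cv_rows["true_group"]).mean()
            )
    return ClassificationTable(
        table=rows,
        confusion=confusion,
        confusion_cv=confusion_cv,
        percent_correct=pct,
        percent_correct_cv=pct_cv,
    )


def _confusion(rows: pd.DataFrame, col: str, groups: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for true_grp, sub in rows.groupby("true_group"):
        counts = sub[col].value_counts()
        for pred_grp, c in counts.items():
            out.loc[true_grp, pred_grp] = 100.0 * c / len(sub)
    return out


def group_distance_tests(
    dataset: ShapeDataset,
    grouping: GroupingSpec = "diet",
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Procrustes distances between group mean shapes, with
    permutation p-values from shuffling the two groups' specimen labels.

    p = (1 + #{permuted distance >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p", RuntimeWarning)
    Y = dataset.require_aligned()
    labels = resolve_grouping(dataset, grouping)
    groups = sorted(g for g in set(labels) if g != "ungrouped")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    dist = pd.DataFrame(0.0, index=groups, columns=groups)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)
    rng = np.random.default_rng(seed)
    for a_i in range(len(groups)):
        for b_i in range(a_i + 1, len(groups)):
            ga, gb = groups[a_i], groups[b_i]
            Ya, Yb = Y[labels == ga], Y[labels == gb]
            na = Ya.shape[0]
            obs = procrustes_distance(Ya.mean(axis=0), Yb.mean(axis=0))
            pool = np.vstack([Ya, Yb])
            exceed = 0
            for _ in range(n_perm):
                idx = rng.permutation(pool.shape[0])
                d = procrustes_distance(
                    pool[idx[:na]].mean(axis=0), pool[idx[na:]].mean(axis=0)
                )
                if d >= obs:
                    exceed += 1
            p = (1 + exceed) / (1 + n_perm)
            dist.loc[ga, gb] = dist.loc[gb, ga] = obs
            pvals.loc[ga, gb] = pvals.loc[gb, ga] = p
    return dist, pvals
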