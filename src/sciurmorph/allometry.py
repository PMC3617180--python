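"""Evolutionary allometry: multivariate regression of shape on centroid size.

Shape (tangent coordinates) is regressed on centroid size across taxon
means. The proportion of shape variation predicted by size is measured in
the Procrustes metric (summed squares over all tangent coordinates), with a
Goodall-style F ratio and a permutation test that shuffles size values
across taxa. Slope/intercept homogeneity between user-defined clades is
tested by ANCOVA on regression scores (projections onto the pooled
allometric axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .datatypes import ShapeDataset, vector_to_shape


@dataclass
class AllometryModel:
    """Fitted multivariate regression of tangent coordinates on size."""

    intercept_shape: np.ndarray  # (2k,)
    slope_vector: np.ndarray  # (2k,) shape change per unit predictor
    percent_predicted: float
    goodall_F: float
    p_permutation: float
    n: int
    predictor: str  # "cs" or "log_cs"
    taxa: list[str] = field(default_factory=list)
    predictor_values: Optional[np.ndarray] = None

    @property
    def percent_residual(self) -> float:
        return 100.0 - self.percent_predicted

    def predict(self, cs: float) -> np.ndarray:
        """Predicted shape (k x 2) at a given centroid size (mm)."""
        x = np.log(cs) if self.predictor == "log_cs" else cs
        return vector_to_shape(self.intercept_shape + self.slope_vector * x)


def _predictor_values(dataset: ShapeDataset, predictor: str) -> np.ndarray:
    cs = dataset.centroid_sizes
    if predictor == "cs":
        return cs
    if predictor == "log_cs":
        return np.log(cs)
    raise ValueError(f"unknown predictor {predictor!r}; use 'cs' or 'log_cs'")


def _percent_predicted(Yc: np.ndarray, xc: np.ndarray) -> tuple[float, np.ndarray]:
    sxx = float(xc @ xc)
    b = (xc @ Yc) / sxx
    ss_pred = sxx * float(b @ b)
    ss_tot = float(np.sum(Yc**2))
    return 100.0 * ss_pred / ss_tot, b


def fit_allometry(
    dataset: ShapeDataset,
    predictor: str = "cs",
    n_perm: int = 9999,
    seed: int = 0,
) -> AllometryModel:
    """Least-squares fit of each tangent coordinate on centroid size.

    ``percent_predicted`` is 100 x (predicted SS / total SS) in the
    Procrustes metric; the Goodall-style F pools all shape dimensions with
    (1, n-2) degrees of freedom; the permutation p shuffles predictor values
    across taxa, p = (1 + #{permuted %predicted >= observed}) / (1 + n_perm).
    """
    Y = dataset.require_aligned()
    x = _predictor_values(dataset, predictor)
    n = dataset.n
    if n < 3:
        raise ValueError("allometry fit needs at least 3 taxa")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant across taxa")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p", RuntimeWarning)

    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    percent, b = _percent_predicted(Yc, xc)
    ss_tot = float(np.sum(Yc**2))
    ss_pred = ss_tot * percent / 100.0
    ss_res = ss_tot - ss_pred
    goodall_F = (ss_pred / 1.0) / (ss_res / (n - 2)) if ss_res > 0 else np.inf

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = rng.permutation(xc)
        perc_p, _ = _percent_predicted(Yc, xp)
        if perc_p >= percent:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    intercept = Y.mean(axis=0) - b * x.mean()
    return AllometryModel(
        intercept_shape=intercept,
        slope_vector=b,
        percent_predicted=percent,
        goodall_F=goodall_F,
        p_permutation=p,
        n=n,
        predictor=predictor,
        taxa=list(dataset.taxa),
        predictor_values=x,
    )


def residual_shapes(model: AllometryModel, dataset: ShapeDataset) -> ShapeDataset:
    """Size-corrected shapes: regression residuals re-expressed about the consensus.

    The returned dataset's tangent rows are consensus + residual, so its
    covariance matrix is the residual covariance the size-corrected ordination
    consumes, and downstream code can keep treating rows as shapes.
    """
    Y = dataset.require_aligned()
    if model.taxa != list(dataset.taxa):
        raise ValueError("model was fitted on a different set of taxa")
    x = _predictor_values(dataset, model.predictor)
    fitted = model.intercept_shape + np.outer(x, model.slope_vector)
    residuals = Y - fitted
    c = np.asarray(dataset.consensus).reshape(-1)
    out = ShapeDataset(
        specimens=list(dataset.specimens),
        consensus=dataset.consensus,
        tangent_coords=residuals + c,
        gpa_converged=dataset.gpa_converged,
        mean_centroid_sizes=dataset.mean_centroid_sizes,
    )
    return out


@dataclass
class HomogeneityReport:
    """ANCOVA on regression scores: clade slope/intercept homogeneity."""

    groups: list[str]
    excluded: list[str]
    slope_F: float
    slope_df: tuple[int, int]
    slope_p: float
    slope_p_perm: float
    intercept_F: float
    intercept_df: tuple[int, int]
    intercept_p: float
    intercept_p_perm: float


def _nested_F(ssr_reduced: float, ssr_full: float, df_diff: int, df_resid: int):
    if ssr_full <= 0:
        return np.inf, 0.0
    F = ((ssr_reduced - ssr_full) / df_diff) / (ssr_full / df_resid)
    from scipy import stats

    return float(F), float(stats.f.sf(F, df_diff, df_resid))


def test_common_allometry(
    dataset: ShapeDataset,
    grouping: Mapping[str, str],
    predictor: str = "cs",
    n_perm: int = 999,
    seed: int = 0,
    min_group_size: int = 3,
) -> HomogeneityReport:
    """Test slope then intercept homogeneity of allometry across clades.

    Shapes are projected onto the pooled (within-group common) allometric
    axis; the resulting one-dimensional regression scores go through a
    standard ANCOVA: a group x size interaction F for slope heterogeneity
    (df = g-1), then, under a common slope, a group F for intercepts
    (df = g-1). Parametric p-values are reported together with residual-
    permutation p-values.
    """
    Y = dataset.require_aligned()
    x = _predictor_values(dataset, predictor)
    labels = np.array([grouping.get(t, "") for t in dataset.taxa])

    counts = pd.Series(labels).value_counts()
    keep_groups = [g for g in counts.index if g and counts[g] >= min_group_size]
    excluded = [g for g in counts.index if g and counts[g] < min_group_size]
    for g in excluded:
        warnings.warn(f"group {g!r} has fewer than {min_group_size} taxa; excluded",
                      RuntimeWarning)
    if len(keep_groups) < 2:
        raise ValueError("need at least 2 groups with enough taxa to compare")
    mask = np.isin(labels, keep_groups)
    Yg, xg, lg = Y[mask], x[mask], labels[mask]
    n = int(mask.sum())
    g = len(keep_groups)

    # pooled common slope: within-group centered regression
    Yw = Yg.copy()
    xw = xg.copy().astype(float)
    for grp in keep_groups:
        m = lg == grp
        Yw[m] -= Yw[m].mean(axis=0)
        xw[m] -= xw[m].mean()
    b_pooled = (xw @ Yw) / float(xw @ xw)
    b_unit = b_pooled / np.linalg.norm(b_pooled)
    scores = Yg @ b_unit

    df = pd.DataFrame({"score": scores, "x": xg, "group": lg})
    full = smf.ols("score ~ C(group) * x", data=df).fit()
    no_int = smf.ols("score ~ C(group) + x", data=df).fit()
    common = smf.ols("score ~ x", data=df).fit()

    slope_df = (g - 1, n - 2 * g)
    slope_F, slope_p = _nested_F(no_int.ssr, full.ssr, *_pair(slope_df))
    int_df = (g - 1, n - g - 1)
    int_F, int_p = _nested_F(common.ssr, no_int.ssr, *_pair(int_df))

    # residual-permutation p-values; hat matrices precomputed for speed
    def _hat(X: np.ndarray) -> np.ndarray:
        return X @ np.linalg.pinv(X)

    dummies = pd.get_dummies(df["group"], dtype=float).to_numpy()
    ones = np.ones((n, 1))
    X_common = np.hstack([ones, xg[:, None]])
    X_noint = np.hstack([dummies, xg[:, None]])
    X_full = np.hstack([dummies, dummies * xg[:, None]])
    H_common, H_noint, H_full = _hat(X_common), _hat(X_noint), _hat(X_full)

    def _ssr(H: np.ndarray, y: np.ndarray) -> float:
        r = y - H @ y
        return float(r @ r)

    rng = np.random.default_rng(seed)
    slope_exceed = 0
    int_exceed = 0
    fitted_noint = no_int.fittedvalues.to_numpy()
    resid_noint = no_int.resid.to_numpy()
    fitted_common = common.fittedvalues.to_numpy()
    resid_common = common.resid.to_numpy()
    for _ in range(n_perm):
        y_s = fitted_noint + rng.permutation(resid_noint)
        F_s, _ = _nested_F(_ssr(H_noint, y_s), _ssr(H_full, y_s), *_pair(slope_df))
        if F_s >= slope_F:
            slope_exceed += 1
        y_i = fitted_common + rng.permutation(resid_common)
        F_i, _ = _nested_F(_ssr(H_common, y_i), _ssr(H_noint, y_i), *_pair(int_df))
        if F_i >= int_F:
            int_exceed += 1

    return HomogeneityReport(
        groups=keep_groups,
        excluded=excluded,
        slope_F=slope_F,
        slope_df=slope_df,
        slope_p=slope_p,
        slope_p_perm=(1 + slope_exceed) / (1 + n_perm) if n_perm else float("nan"),
        intercept_F=int_F,
        intercept_df=int_df,
        intercept_p=int_p,
        intercept_p_perm=(1 + int_exceed) / (1 + n_perm) if n_perm else float("nan"),
    )


def _pair(df: tuple[int, int]) -> tuple[int, int]:
    return df[0], df[1]
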