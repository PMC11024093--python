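"""Shape-space analysis of pooled calcium-transient trajectories.

Each cell's normalized trajectory is treated as one vectorial
observation and the pooled set (both micropattern geometries, all
agonist concentrations) is decomposed by full-SVD PCA.  The top three
components define "PC space".  Per agonist concentration, group mean
vectors in PC space are compared with a Wilks'-lambda MANOVA
(Bonferroni-adjusted across concentrations) and an LDA fitted on the
same scores gives the direction that best separates the geometries.
Cluster centroids can be projected back into trajectory space for
visual comparison of the average responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "ShapeSpaceModel",
    "GroupComparison",
    "fit_pca",
    "project",
    "reconstruct_mean",
    "compare_groups",
]

N_COMPONENTS = 3


@dataclass
class ShapeSpaceModel:
    mean: np.ndarray                      # (n_frames,)
    components: np.ndarray                # (3, n_frames), orthonormal rows
    explained_variance_ratio: np.ndarray  # (3,), non-increasing
    scores: np.ndarray                    # (n_cells, 3)
    labels: np.ndarray | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Wilks'-lambda MANOVA outcome plus the LDA separation direction."""

    wilks_lambda: float
    f_stat: float
    df_num: float
    df_den: float
    p_raw: float
    p_bonferroni: float
    lda_weights: np.ndarray
    n_per_group: dict


def fit_pca(values: np.ndarray, labels=None, n_components: int = N_COMPONENTS) -> ShapeSpaceModel:
    """Mean-centered full-SVD PCA of pooled trajectories, top components kept.

    Component signs are fixed so each component's largest-magnitude
    loading is positive (SVD sign is otherwise arbitrary).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be 2-D (cells x frames)")
    if X.shape[0] < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} cells")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    for k in range(n_components):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    return ShapeSpaceModel(
        mean=pca.mean_,
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores,
        labels=None if labels is None else np.asarray(labels),
    )


def project(trajectories: np.ndarray, model: ShapeSpaceModel) -> np.ndarray:
    """Scores of (possibly new) trajectories: centered inner products."""
    X = np.atleast_2d(np.asarray(trajectories, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ValueError("trajectory length does not match the fitted model")
    return (X - model.mean) @ model.components.T


def reconstruct_mean(scores: np.ndarray, model: ShapeSpaceModel) -> np.ndarray:
    """Back-project PC-space coordinates into trajectory space."""
    s = np.asarray(scores, dtype=float)
    return model.mean + s @ model.components


def _manova_two_group(scores: np.ndarray, indicator: np.ndarray):
    exog = np.column_stack([np.ones(len(scores)), indicator])
    mv = MANOVA(scores, exog)
    contrast = np.array([[0.0, 1.0]])
    res = mv.mv_test(hypotheses=[("group", contrast, None)])
    tbl = res.results["group"]["stat"]
    row = tbl.loc["Wilks' lambda"]
    return (
        float(row["Value"]),
        float(row["F Value"]),
        float(row["Num DF"]),
        float(row["Den DF"]),
        float(row["Pr > F"]),
    )


def compare_groups(
    scores: np.ndarray,
    labels,
    concentrations,
    levels=None,
) -> dict:
    """Per-concentration two-group comparison in PC space.

    ``labels`` are the shape-group labels and ``concentrations`` the
    per-cell agonist dose; the MANOVA runs separately at each dose level
    and raw p-values are Bonferroni-multiplied by the number of levels
    tested.  LDA (priors proportional to group sizes) is fitted on the
    same scores; its weight vector is reported as the separation
    direction.  Returns ``{level: GroupComparison}``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    concentrations = np.asarray(concentrations)
    if levels is None:
        levels = pd.unique(concentrations)
    levels = list(levels)
    n_tests = len(levels)
    out = {}
    for level in levels:
        sel = concentrations == level
        sub, lab = scores[sel], labels[sel]
        groups = pd.unique(lab)
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups at level {level!r}, got {len(groups)}")
        counts = {g: int((lab == g).sum()) for g in groups}
        if min(counts.values()) < 4:
            raise ValueError(f"need >= 4 cells per group at level {level!r}")
        indicator = (lab == groups[1]).astype(float)
        try:
            wilks, fval, dfn, dfd, p = _manova_two_group(sub, indicator)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular within-group covariance at level {level!r}") from err
        lda = LinearDiscriminantAnalysis()
        lda.fit(sub, lab)
        out[level] = GroupComparison(
            wilks_lambda=wilks,
            f_stat=fval,
            df_num=dfn,
            df_den=dfd,
            p_raw=p,
            p_bonferroni=min(1.0, p * n_tests),
            lda_weights=lda.coef_[0].copy(),
            n_per_group=counts,
        )
    return out
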