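"""Epithelial-mesenchymal (EPI-MES) tumor signature scoring.

Starting from a tumors x genes log2 expression matrix, every gene is
z-scored across tumors.  The curated epithelial and mesenchymal gene
lists are refined by keeping only members whose z-score profile
correlates with the unweighted mean z of their full list at Pearson
r > 0.5.  A tumor's EPI-MES score is the mean z over the refined
epithelial signature minus the mean z over the refined mesenchymal
signature; tumors are then stratified into rank quintiles labelled
H-MES, L-MES, Ambig, L-EPI, H-EPI from most mesenchymal to most
epithelial.  Helpers compute per-stratum marker correlation panels,
average-linkage/Manhattan clustering of correlation matrices, and
comparative-Ct (2^-ddCt) qRT-PCR quantitation.

The gene lists ship as a plain-text resource; the printed epithelial
list repeats one keratin symbol, so the loader de-duplicates while
preserving order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "GeneLists",
    "EpiMesResult",
    "load_gene_lists",
    "zscore_genes",
    "refine_signature",
    "score_and_stratify",
    "marker_correlations",
    "cluster_correlation_matrix",
    "ddct_quantitation",
    "QUINTILE_LABELS",
    "REFINE_R_THRESHOLD",
]

#: Quintile labels ordered from most mesenchymal to most epithelial.
QUINTILE_LABELS = ("H-MES", "L-MES", "Ambig", "L-EPI", "H-EPI")
#: Pearson threshold (strict) for signature refinement.
REFINE_R_THRESHOLD = 0.5


@dataclass(frozen=True)
class GeneLists:
    epithelial: tuple[str, ...]
    mesenchymal: tuple[str, ...]
    subtype_markers: tuple[str, ...]
    refined_epi: tuple[str, ...] = ()
    refined_mes: tuple[str, ...] = ()

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.epithelial + self.mesenchymal + self.subtype_markers


@dataclass
class EpiMesResult:
    """Per-tumor scores and quintile labels plus the refined signatures."""

    table: pd.DataFrame  # columns epi_z, mes_z, score, quintile
    refined_epi: tuple[str, ...]
    refined_mes: tuple[str, ...]


def load_gene_lists() -> GeneLists:
    """Load the packaged signature gene lists (order-preserving, de-duplicated)."""
    path = resources.files("calshape").joinpath("data/gene_lists.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")

    def unique(name):
        return tuple(dict.fromkeys(df.loc[df["list"] == name, "gene"]))

    return GeneLists(
        epithelial=unique("epithelial"),
        mesenchymal=unique("mesenchymal"),
        subtype_markers=unique("subtype_marker"),
    )


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene cross-tumor z-scores (sample sd, n-1 denominator).

    Genes with zero cross-tumor variance or any missing value cannot be
    z-scored; they are dropped with a warning rather than zero-filled.
    """
    if len(expr) < 2:
        raise ValueError("need at least 2 tumors to z-score")
    has_na = expr.columns[expr.isna().any()]
    if len(has_na):
        warnings.warn(f"dropping {len(has_na)} gene(s) with missing values: "
                      f"{list(has_na[:5])}...", stacklevel=2)
        expr = expr.drop(columns=has_na)
    sd = expr.std(axis=0, ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance gene(s): {list(flat[:5])}",
                      stacklevel=2)
        expr = expr.drop(columns=flat)
        sd = sd.drop(flat)
    return (expr - expr.mean(axis=0)) / sd


def refine_signature(z: pd.DataFrame, genes) -> tuple[str, ...]:
    """Keep list members with Pearson r > 0.5 to the full list's mean z-score.

    The reference profile is the unweighted mean z over every available
    list gene (the candidate gene included).
    """
    present = [g for g in genes if g in z.columns]
    if not present:
        raise ValueError("none of the signature genes are present in the matrix")
    reference = z[present].mean(axis=1)
    kept = tuple(
        g for g in present
        if stats.pearsonr(z[g], reference).statistic > REFINE_R_THRESHOLD
    )
    if not kept:
        raise ValueError("signature refinement removed every gene")
    return kept


def score_and_stratify(z: pd.DataFrame, refined_epi, refined_mes) -> EpiMesResult:
    """EPI-MES score per tumor and rank-quintile stratification.

    score = mean z over the refined epithelial genes minus mean z over
    the refined mesenchymal genes.  Tumors are sorted by score (stable)
    and split into five contiguous, balanced groups; the lowest-score
    fifth is labelled H-MES and the highest H-EPI.
    """
    refined_epi = list(refined_epi)
    refined_mes = list(refined_mes)
    if not refined_epi or not refined_mes:
        raise ValueError("refined signatures must be non-empty")
    if len(z) < 5:
        raise ValueError("need at least 5 tumors for quintiles")
    epi_z = z[refined_epi].mean(axis=1)
    mes_z = z[refined_mes].mean(axis=1)
    score = epi_z - mes_z
    order = score.to_numpy().argsort(kind="stable")
    labels = np.empty(len(score), dtype=object)
    for lab, chunk in zip(QUINTILE_LABELS, np.array_split(order, 5)):
        labels[chunk] = lab
    table = pd.DataFrame(
        {"epi_z": epi_z, "mes_z": mes_z, "score": score,
         "quintile": pd.Categorical(labels, categories=list(QUINTILE_LABELS), ordered=True)},
        index=z.index,
    )
    return EpiMesResult(table=table, refined_epi=tuple(refined_epi), refined_mes=tuple(refined_mes))


def marker_correlations(expr: pd.DataFrame, target: str, markers, strata: pd.Series) -> pd.DataFrame:
    """Pearson r and raw two-sided p of ``target`` vs each marker per stratum.

    ``strata`` maps tumor -> stratum label (e.g. the quintile).  Strata
    with fewer than 3 tumors yield NaN r/p and ``computable = False``.
    No multiplicity adjustment is applied.
    """
    if target not in expr.columns:
        raise ValueError(f"target gene {target!r} not in matrix")
    missing = [m for m in markers if m not in expr.columns]
    if missing:
        raise ValueError(f"marker genes not in matrix: {missing}")
    rows = []
    strata = strata.reindex(expr.index)
    for stratum in pd.unique(strata.dropna()):
        sub = expr.loc[strata == stratum]
        for m in markers:
            if len(sub) < 3:
                rows.append((stratum, m, np.nan, np.nan, len(sub), False))
                continue
            r, p = stats.pearsonr(sub[target], sub[m])
            rows.append((stratum, m, float(r), float(p), len(sub), True))
    return pd.DataFrame(rows, columns=["stratum", "marker", "r", "p", "n", "computable"])


def cluster_correlation_matrix(corr: pd.DataFrame, k: int) -> tuple[list, pd.Series]:
    """Average-linkage hierarchical clustering of correlation-matrix rows.

    Distances are Manhattan (city-block) between rows of the square
    symmetric correlation matrix.  Returns the dendrogram leaf order
    (gene names) and the assignment of each gene to one of ``k`` groups
    obtained by cutting the tree.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if k > corr.shape[0] or k < 1:
        raise ValueError("k must be between 1 and the number of genes")
    Z = hierarchy.linkage(corr.to_numpy(), method="average", metric="cityblock")
    order = [corr.index[i] for i in hierarchy.leaves_list(Z)]
    groups = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return order, pd.Series(groups, index=corr.index, name="group")


def ddct_quantitation(delta_delta_ct):
    """Comparative-Ct quantities: fold change 2^-ddCt, % mRNA remaining, -ddCt."""
    ddct = np.asarray(delta_delta_ct, dtype=float)
    if not np.all(np.isfinite(ddct)):
        raise ValueError("delta_delta_ct must be finite")
    fold = 2.0 ** (-ddct)
    out = {"fold_change": fold, "percent_remaining": fold * 100.0, "relative_mrna": -ddct}
    if ddct.ndim == 0:
        out = {key: float(val) for key, val in out.items()}
    return out
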