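"""PCA of genotype-mean anthocyanin trajectories.

Genotype-average estimated anthocyanin from every site-year is compiled into
one matrix (rows = genotypes, columns = (site, year, date) time points) and
reduced by column-centered SVD PCA. Per-time-point score contributions show
which site-years drive the separation of genotypes along a component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PcaResult", "build_matrix", "run_pca", "pc_scores_over_time"]


@dataclass
class PcaResult:
    loadings: pd.DataFrame          # components × columns
    scores: pd.DataFrame            # genotypes × components
    explained_variance: np.ndarray  # eigenvalues
    explained_fraction: np.ndarray  # fractions in [0, 1], summing to 1
    column_means: pd.Series
    scaled: bool = False
    column_scales: pd.Series = None


def build_matrix(genotype_series: pd.DataFrame,
                 complete_columns_only: bool = True,
                 value_col: str = "value") -> pd.DataFrame:
    """Genotype × (site, year, date) matrix of mean trait values.

    ``genotype_series`` columns: genotype, site, year, date, <value_col>.
    With ``complete_columns_only`` any time point missing for at least one
    genotype is dropped (count logged); otherwise missing entries are mean-
    imputed per column (exploratory fallback, clearly second-class).
    """
    df = genotype_series.copy()
    df["date"] = pd.to_datetime(df["date"])
    mat = df.pivot_table(index="genotype", columns=["site", "year", "date"],
                         values=value_col, aggfunc="mean")
    mat = mat.sort_index(axis=1)
    if complete_columns_only:
        complete = mat.notna().all(axis=0)
        dropped = int((~complete).sum())
        if dropped:
            logger.info("build_matrix: dropped %d incomplete columns", dropped)
        mat = mat.loc[:, complete]
    else:
        mat = mat.apply(lambda c: c.fillna(c.mean()), axis=0)
    if mat.shape[1] < 2:
        raise ValueError("fewer than 2 usable time-point columns")
    return mat


def run_pca(matrix: pd.DataFrame, center: bool = True,
            scale: bool = False) -> PcaResult:
    """Column-centered (optionally scaled) SVD PCA of the trait matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive. Explained-variance fractions sum to 1; the scores'
    variances (ddof=1 over genotypes) equal the eigenvalues.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    sc = np.ones(X.shape[1])
    if scale:
        sc = Xc.std(axis=0, ddof=1)
        if np.any(sc == 0):
            raise ValueError("zero-variance column with scale=True")
        Xc = Xc / sc
    if not np.any(Xc):
        raise ValueError("zero-variance matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_comp = min(X.shape[0] - 1 if center else X.shape[0], X.shape[1])
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_comp):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eig = s ** 2 / (X.shape[0] - 1)
    frac = s ** 2 / (s ** 2).sum()
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        loadings=pd.DataFrame(Vt, index=comp_names, columns=matrix.columns),
        scores=pd.DataFrame(U * s, index=matrix.index, columns=comp_names),
        explained_variance=eig,
        explained_fraction=frac,
        column_means=pd.Series(mu, index=matrix.columns),
        scaled=scale,
        column_scales=pd.Series(sc, index=matrix.columns),
    )


def pc_scores_over_time(matrix: pd.DataFrame, pca: PcaResult,
                        component: int = 1) -> pd.DataFrame:
    """Per-time-point contribution of each column to the genotype PC scores.

    contribution[g, t] = loading[t] × centered_value[g, t]; summing over t
    recovers genotype g's score on the component exactly. Index: genotypes;
    columns: the matrix's (site, year, date) columns.
    """
    name = f"PC{component}"
    if name not in pca.loadings.index:
        raise IndexError(f"component {component} out of range")
    Xc = (matrix - pca.column_means) / pca.column_scales
    contrib = Xc * pca.loadings.loc[name]
    return contrib
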