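"""Cross-species synthesis of F-versus-M divergence.

A species-by-feature matrix is assembled from per-gene nucleotide distances
and per-PCG amino-acid distances; principal component analysis summarises
the overall divergence structure and rank-concordance tests (Spearman rho,
Kendall tau) ask whether two taxon groups order the genes by divergence in
related ways.

The package ships a transcription of the published 15-species DUI-bivalve
distance table (Jin–Nei nucleotide and Kimura amino-acid, x100) as
``data/bivalve_distances.tsv``; :func:`load_distance_table` reads it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureMatrix",
    "PcaResult",
    "RankConcordance",
    "load_distance_table",
    "build_feature_matrix",
    "pca",
    "rank_concordance",
    "GENES_NT",
    "GENES_AA",
]

#: Single-gene nucleotide distance columns (13 PCGs + 2 rRNAs) and the
#: per-PCG amino-acid columns of the cross-species table.
GENES_NT = [
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb", "nad1", "nad2",
    "nad3", "nad4", "nad4L", "nad5", "nad6", "rrnL", "rrnS",
]
GENES_AA = GENES_NT[:13]


def load_distance_table(path=None) -> pd.DataFrame:
    """Read a species-by-gene distance table (TSV, blanks = missing).

    Without ``path`` the packaged 15-species DUI-bivalve table is loaded.
    The frame is indexed by species; ``group`` holds the taxon grouping used
    for group averages.
    """
    if path is None:
        ref = resources.files("mitopair.data").joinpath("bivalve_distances.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("species")


@dataclass
class FeatureMatrix:
    values: np.ndarray  # no missing entries after policy application
    rows: list[str]
    columns: list[str]
    dropped_columns: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.columns)


def build_feature_matrix(
    table: pd.DataFrame,
    missing_policy: str = "mean",
    nt_genes: list[str] | None = None,
    aa_genes: list[str] | None = None,
) -> FeatureMatrix:
    """Species x (per-gene nt distance + per-PCG aa distance) matrix.

    ``missing_policy`` is ``"mean"`` (impute a missing cell with its column
    mean) or ``"drop"`` (drop any column with a missing cell). Columns that
    are entirely missing are always dropped.
    """
    nt_genes = GENES_NT if nt_genes is None else nt_genes
    aa_genes = GENES_AA if aa_genes is None else aa_genes
    cols = [f"nt_{g}" for g in nt_genes] + [f"aa_{g}" for g in aa_genes]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"distance table lacks columns {missing}")
    X = table[cols].to_numpy(dtype=float)
    keep = np.ones(X.shape[1], dtype=bool)
    nan_mask = np.isnan(X)
    keep &= ~nan_mask.all(axis=0)
    if missing_policy == "drop":
        keep &= ~nan_mask.any(axis=0)
    elif missing_policy == "mean":
        col_means = np.array(
            [np.nanmean(X[:, j]) if keep[j] else 0.0 for j in range(X.shape[1])]
        )
        X = np.where(nan_mask, col_means, X)
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    dropped = [c for c, k in zip(cols, keep) if not k]
    return FeatureMatrix(
        values=X[:, keep],
        rows=list(table.index),
        columns=[c for c, k in zip(cols, keep) if k],
        dropped_columns=dropped,
    )


@dataclass
class PcaResult:
    variance_pct: np.ndarray  # per component, non-increasing, sums to 100
    scores: pd.DataFrame  # species x components
    loadings: pd.DataFrame  # columns x components
    standardized: bool

    @property
    def n_components(self) -> int:
        return len(self.variance_pct)


def pca(matrix: FeatureMatrix, standardize: bool = False) -> PcaResult:
    """Principal components of the feature matrix via eigen-decomposition.

    Columns are centered; with ``standardize`` they are also scaled to unit
    variance (correlation PCA). The default is covariance PCA, which is the
    configuration under which the packaged cross-species table reproduces
    the published first-component variance share. Components are ordered by
    eigenvalue; the sign of each is fixed so that its largest-magnitude
    loading is positive.
    """
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 rows and 1 column")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        zero = [c for c, s in zip(matrix.columns, sd) if s == 0.0]
        if zero:
            raise ValueError(f"zero-variance columns under standardization: {zero}")
        Xc = Xc / sd
    cov = Xc.T @ Xc / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs
    comp = [f"PC{i + 1}" for i in range(len(evals))]
    return PcaResult(
        variance_pct=100.0 * evals / evals.sum(),
        scores=pd.DataFrame(scores, index=matrix.rows, columns=comp),
        loadings=pd.DataFrame(evecs, index=matrix.columns, columns=comp),
        standardized=standardize,
    )


@dataclass(frozen=True)
class RankConcordance:
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    n: int
    tie_note: str = "average ranks for ties"


def rank_concordance(x, y) -> RankConcordance:
    """Spearman and Kendall rank concordance between two gene orderings.

    Spearman p uses the t approximation; Kendall p is exact for n <= 10
    without ties and normal-approximate otherwise (scipy's 'auto' policy).
    Invariant under strictly monotone transforms of either input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 items to rank")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant vector has no ranking")
    rho, rho_p = stats.spearmanr(x, y)
    tau, tau_p = stats.kendalltau(x, y)
    return RankConcordance(
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        kendall_tau=float(tau),
        kendall_p=float(tau_p),
        n=len(x),
    )
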