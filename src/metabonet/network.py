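"""Signed weighted-network construction: correlation, soft-threshold
adjacency, scale-free topology fit and the topological overlap matrix.

The signed adjacency is a_ij = ((1 + cor_ij)/2)^beta, so anti-correlated
features get weight near 0 and the matrix is non-negative; the soft
threshold beta is picked as the lowest candidate whose scale-free fit index
reaches the target (0.90 by default).  TOM_ij combines the direct connection
a_ij with the shared-neighbour term sum_u a_iu a_uj.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_POWERS = tuple(range(1, 21))


@dataclass(frozen=True)
class NetworkConfig:
    """Soft-threshold power, network type and correlation method."""

    power: float = 4.0
    network_type: str = "signed"
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.network_type not in {"signed", "unsigned"}:
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if self.correlation_method not in {"pearson", "spearman"}:
            raise ValueError(
                f"unknown correlation_method {self.correlation_method!r}")


@dataclass
class CorrelationMatrix:
    """Symmetric feature × feature correlation matrix with its method tag."""

    values: pd.DataFrame
    method: str


@dataclass
class AdjacencyMatrix:
    """Feature × feature soft-thresholded connection weights in [0, 1]."""

    values: pd.DataFrame
    config: NetworkConfig


@dataclass
class TOMMatrix:
    """Topological overlap similarities; ``dissimilarity`` gives 1 − TOM."""

    values: pd.DataFrame

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.values


@dataclass
class ScaleFreeFit:
    """Scale-free topology fit of one adjacency matrix.

    ``fit_index`` is −sign(slope)·R² of the regression of log10 p(k) on
    log10 k over non-empty connectivity bins, so a positive-slope (non
    scale-free) fit can never reach a positive target.
    """

    fit_index: float
    slope: float
    r_squared: float
    mean_k: float
    median_k: float
    max_k: float
    n_bins: int


def correlation_matrix(table: FeatureTable, method: str = "pearson") -> CorrelationMatrix:
    """All pairwise feature–feature correlations across samples."""
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    X = table.values()
    if np.isnan(X).any():
        raise ValueError("correlation_matrix requires a table with no missing entries")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [fid for fid, s in zip(table.feature_ids, sd) if s == 0]
        raise ValueError(f"zero-variance features: {bad}")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    ids = table.feature_ids
    return CorrelationMatrix(pd.DataFrame(C, index=ids, columns=ids), method)


def adjacency(cor: CorrelationMatrix, config: NetworkConfig | None = None) -> AdjacencyMatrix:
    """Soft-threshold the correlations into connection weights.

    signed:   a_ij = ((1 + cor_ij)/2)^beta   (maps −1→0, 0→(1/2)^beta, 1→1)
    unsigned: a_ij = |cor_ij|^beta
    """
    config = config or NetworkConfig()
    C = cor.values.to_numpy(dtype=float)
    if config.network_type == "signed":
        A = ((1.0 + C) / 2.0) ** config.power
    else:
        A = np.abs(C) ** config.power
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(
        pd.DataFrame(A, index=cor.values.index, columns=cor.values.columns),
        config)


def connectivity(adj: AdjacencyMatrix) -> np.ndarray:
    """Whole-network connectivity k_i = Σ_{j≠i} a_ij (self excluded)."""
    A = adj.values.to_numpy(dtype=float)
    return A.sum(axis=1) - np.diag(A)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit index of an adjacency matrix.

    Connectivities are binned into ``n_bins`` equal-width bins; the
    frequency per non-empty bin is regressed (least squares) against the
    bin's mean connectivity on log10–log10 axes.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    k = connectivity(adj)
    if np.ptp(k) == 0:
        raise ValueError("degenerate degree distribution: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1], right=False), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        mean_k = members.mean()
        freq = members.size / k.size
        if mean_k <= 0 or freq <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_p.append(np.log10(freq))
    log_k = np.asarray(log_k)
    log_p = np.asarray(log_p)
    if log_k.size < 2 or np.ptp(log_k) == 0:
        raise ValueError("too few distinct connectivity bins for a regression")
    slope, intercept = np.polyfit(log_k, log_p, 1)
    resid = log_p - (slope * log_k + intercept)
    ss_tot = np.sum((log_p - log_p.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
    fit_index = -np.sign(slope) * r2 if slope != 0 else r2
    return ScaleFreeFit(float(fit_index), float(slope), float(r2),
                        float(k.mean()), float(np.median(k)), float(k.max()),
                        n_bins)


def pick_soft_threshold(
    table: FeatureTable,
    candidate_powers=DEFAULT_POWERS,
    target_fit: float = 0.90,
    network_type: str = "signed",
    correlation_method: str = "pearson",
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame, bool]:
    """Pick the lowest power whose scale-free fit index reaches ``target_fit``.

    Returns ``(power, fit_table, reached)``.  If no candidate reaches the
    target, the candidate with the maximal fit index is returned with
    ``reached=False``.  The fit table has one row per candidate power with
    columns power, fit_index, slope, mean_k, median_k, max_k.
    """
    powers = list(candidate_powers)
    if not powers:
        raise ValueError("candidate_powers must be non-empty")
    if sorted(powers) != powers:
        raise ValueError("candidate_powers must be ascending")
    cor = correlation_matrix(table, correlation_method)
    rows = []
    for p in powers:
        adj = adjacency(cor, NetworkConfig(p, network_type, correlation_method))
        fit = scale_free_fit(adj, n_bins=n_bins)
        rows.append({"power": p, "fit_index": fit.fit_index, "slope": fit.slope,
                     "mean_k": fit.mean_k, "median_k": fit.median_k,
                     "max_k": fit.max_k})
    fit_table = pd.DataFrame(rows)
    qualifying = fit_table[fit_table["fit_index"] >= target_fit]
    if len(qualifying):
        chosen = float(qualifying.iloc[0]["power"])
        return chosen, fit_table, True
    best = fit_table.loc[fit_table["fit_index"].idxmax(), "power"]
    logger.warning("no candidate power reached fit %.2f; returning best %s",
                   target_fit, best)
    return float(best), fit_table, False


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap matrix of a non-negative adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu; diagonal set to 1.
    """
    A = adj.values.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # L_ii includes a_iu^2 terms; off-diagonal L_ij already sums u≠i,j
    num = L + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(denom > 0, num / denom, 0.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    return TOMMatrix(pd.DataFrame(T, index=adj.values.index,
                                  columns=adj.values.columns))
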