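"""Module detection: TOM clustering, static tree cut, eigenmetabolites,
the minimum-kME membership filter and size-ordered color labels.

Assignment follows the emphasis of the analysis this package implements:
clusters come from a static quantile cut of the average-linkage tree on
1 − TOM, small clusters dissolve to grey, and the decisive filter is
iterative removal of members whose correlation with their module's
eigenmetabolite (kME) falls below ``min_kme_to_stay`` (0.7 by default).
A bit-for-bit dynamic-hybrid tree cut is deliberately not reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

from .io import FeatureTable
from .network import TOMMatrix

logger = logging.getLogger(__name__)

GREY = "grey"

#: canonical module palette, assigned by decreasing module size
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)


@dataclass(frozen=True)
class DetectionConfig:
    min_cluster_size: int = 20
    cut_quantile: float = 0.99
    min_kme_to_stay: float = 0.7
    merge_cut_height: float = 0.25
    merge_modules: bool = False
    max_kme_iterations: int = 10

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0.0 < self.cut_quantile <= 1.0:
            raise ValueError("cut_quantile must be in (0, 1]")
        if not 0.0 <= self.min_kme_to_stay <= 1.0:
            raise ValueError("min_kme_to_stay must be in [0, 1]")
        if self.max_kme_iterations < 1:
            raise ValueError("max_kme_iterations must be >= 1")


@dataclass
class ModuleAssignment:
    """feature → module label mapping; ``grey`` is reserved for unassigned."""

    labels: pd.Series  # index = feature IDs, values = module labels
    converged: bool = True

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def module_names(self) -> list[str]:
        """Non-grey module labels, largest module first."""
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class Eigenmetabolites:
    """Samples × modules matrix of first-PC summary profiles.

    Each eigenmetabolite (ME) has zero mean and unit variance across
    samples, and its sign is oriented so that it correlates non-negatively
    with the module's mean standardized profile.
    """

    values: pd.DataFrame  # samples × modules
    variance_explained: pd.Series  # per module

    @property
    def module_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MembershipMatrix:
    """Features × modules kME values (correlation of feature with each ME)."""

    values: pd.DataFrame
    labels: pd.Series

    def own_module_kme(self) -> pd.Series:
        """kME of each non-grey feature with its own module's ME."""
        out = {}
        for fid, module in self.labels.items():
            if module != GREY and module in self.values.columns:
                out[fid] = self.values.at[fid, module]
        return pd.Series(out, dtype=float)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def cluster_features(tom: TOMMatrix) -> np.ndarray:
    """Average-linkage tree on the TOM dissimilarity (scipy linkage matrix)."""
    D = tom.dissimilarity.to_numpy(dtype=float)
    if D.shape[0] < 3:
        raise ValueError("cluster_features requires at least 3 features")
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


def initial_labels(tree: np.ndarray, tom: TOMMatrix,
                   config: DetectionConfig | None = None) -> ModuleAssignment:
    """Cut the feature tree at the height quantile; dissolve small clusters.

    The static cut height is the ``cut_quantile`` quantile of the merge
    heights; clusters smaller than ``min_cluster_size`` go to grey.
    """
    config = config or DetectionConfig()
    ids = list(tom.values.index)
    heights = tree[:, 2]
    cut = float(np.quantile(heights, config.cut_quantile))
    flat = fcluster(tree, t=cut, criterion="distance")
    labels = pd.Series(flat.astype(str), index=ids)
    sizes = labels.value_counts()
    small = sizes[sizes < config.min_cluster_size].index
    labels[labels.isin(small)] = GREY
    if (labels == GREY).all():
        logger.warning("initial_labels: every feature is grey at cut %.3f", cut)
    # provisional numeric labels -> stable provisional names by cluster id
    mapping = {lab: f"M{lab}" for lab in labels.unique() if lab != GREY}
    labels = labels.replace(mapping)
    return ModuleAssignment(labels)


def eigenmetabolites(table: FeatureTable, labels: ModuleAssignment) -> Eigenmetabolites:
    """First principal component of each module's standardized submatrix.

    Per non-grey module: member profiles are z-scored across samples, the
    first left singular vector of the resulting samples × members matrix is
    rescaled to unit variance, and its sign is chosen so it correlates
    non-negatively with the module's mean standardized profile.  Variance
    explained is the first squared singular value over the total.
    """
    X = table.values()
    index = {fid: j for j, fid in enumerate(table.feature_ids)}
    me_cols, var_exp = {}, {}
    for module in labels.module_names:
        members = labels.members(module)
        cols = [index[f] for f in members]
        Z = _standardize(X[:, cols])
        if len(cols) == 1:
            logger.warning("module %s has a single member", module)
            me = Z[:, 0]
            var_exp[module] = 1.0
        else:
            U, s, _ = np.linalg.svd(Z, full_matrices=False)
            me = U[:, 0]
            var_exp[module] = float(s[0] ** 2 / np.sum(s ** 2))
        me = me - me.mean()
        sd = me.std(ddof=1)
        if sd > 0:
            me = me / sd
        anchor = Z.mean(axis=1)
        if np.dot(me, anchor) < 0:
            me = -me
        me_cols[module] = me
    values = pd.DataFrame(me_cols, index=table.sample_ids)
    return Eigenmetabolites(values, pd.Series(var_exp, dtype=float))


def kme(table: FeatureTable, me: Eigenmetabolites,
        labels: ModuleAssignment | None = None) -> MembershipMatrix:
    """Correlation of every feature profile with every module ME."""
    X = _standardize(table.values())
    M = me.values.to_numpy(dtype=float)
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    n = X.shape[0]
    K = X.T @ M / (n - 1)
    K = np.clip(K, -1.0, 1.0)
    values = pd.DataFrame(K, index=table.feature_ids, columns=me.module_names)
    if labels is None:
        labels = pd.Series(GREY, index=table.feature_ids)
    else:
        labels = labels.labels
    return MembershipMatrix(values, labels)


def enforce_min_kme(table: FeatureTable, labels: ModuleAssignment,
                    config: DetectionConfig | None = None) -> ModuleAssignment:
    """Iteratively move low-membership features to grey until stable.

    Each pass recomputes module MEs and kME, sends any non-grey feature with
    own-module kME below ``min_kme_to_stay`` to grey, and dissolves modules
    shrinking below ``min_cluster_size``.  Converges when the label vector
    is unchanged; capped at ``max_kme_iterations`` passes.
    """
    config = config or DetectionConfig()
    current = labels.labels.copy()
    converged = False
    for _ in range(config.max_kme_iterations):
        assignment = ModuleAssignment(current.copy())
        if not assignment.module_names:
            converged = True
            break
        me = eigenmetabolites(table, assignment)
        mm = kme(table, me, assignment)
        new = current.copy()
        for fid, module in current.items():
            if module == GREY:
                continue
            if mm.values.at[fid, module] < config.min_kme_to_stay:
                new[fid] = GREY
        sizes = new.value_counts()
        for module in sizes.index:
            if module != GREY and sizes[module] < config.min_cluster_size:
                new[new == module] = GREY
        if new.equals(current):
            converged = True
            break
        current = new
    if not converged:
        logger.warning("enforce_min_kme: not converged after %d iterations",
                       config.max_kme_iterations)
    return ModuleAssignment(current, converged=converged)


def merge_close_modules(table: FeatureTable, labels: ModuleAssignment,
                        config: DetectionConfig | None = None) -> ModuleAssignment:
    """Merge modules whose ME dissimilarity is below ``merge_cut_height``.

    Closest pair first, recomputing MEs after each merge.  Off by default
    (``config.merge_modules``); callers invoke this explicitly.
    """
    config = config or DetectionConfig()
    current = ModuleAssignment(labels.labels.copy())
    while len(current.module_names) >= 2:
        me = eigenmetabolites(table, current)
        C = np.corrcoef(me.values.to_numpy(dtype=float), rowvar=False)
        names = me.module_names
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= config.merge_cut_height:
            break
        a, b = sorted((names[i], names[j]),
                      key=lambda m: (-len(current.members(m)), m))
        new = current.labels.copy()
        new[new == b] = a
        current = ModuleAssignment(new)
        logger.info("merged module %s into %s (ME cor %.3f)", b, a, C[i, j])
    return current


def assign_colors(labels: ModuleAssignment) -> ModuleAssignment:
    """Rename non-grey modules by decreasing size through the color palette.

    Ties are broken by the lexicographically smallest member feature ID;
    modules beyond the palette get indexed names ("module21", ...).
    """
    sizes = labels.sizes()
    modules = [m for m in sizes.index if m != GREY]
    order = sorted(modules,
                   key=lambda m: (-sizes[m], min(labels.members(m))))
    mapping = {}
    for rank, module in enumerate(order):
        if rank < len(COLOR_PALETTE):
            mapping[module] = COLOR_PALETTE[rank]
        else:
            mapping[module] = f"module{rank + 1}"
    new = labels.labels.replace(mapping)
    return ModuleAssignment(new, converged=labels.converged)


def detect_modules(table: FeatureTable, tom: TOMMatrix,
                   config: DetectionConfig | None = None,
                   max_rounds: int = 10) -> ModuleAssignment:
    """Full detection: iterated (cluster → static cut → kME filter) → colors.

    A static cut of an average-linkage tree tends to lump several
    co-abundance blocks into one cluster, of which the kME filter keeps only
    the block dominating the cluster's first principal component.  Detection
    therefore extracts modules in rounds: after each kME-filter pass the
    still-unassigned (grey) features are re-clustered on their TOM submatrix
    and cut again, until a round yields no new module.  Each round uses
    exactly the static-cut + size-rule + kME-filter primitives; a final
    global kME pass re-asserts the membership contract over the union.
    """
    config = config or DetectionConfig()
    fallback = [q for q in np.arange(0.95, 0.29, -0.05)
                if q < config.cut_quantile]
    quantiles = [config.cut_quantile] + [round(q, 2) for q in fallback]
    combined = pd.Series(GREY, index=tom.values.index, dtype=object)
    remaining = list(tom.values.index)
    for round_no in range(max_rounds):
        if len(remaining) < max(3, config.min_cluster_size):
            break
        sub_tom = TOMMatrix(tom.values.loc[remaining, remaining])
        sub_table = table.subset_features(remaining)
        tree = cluster_features(sub_tom)
        filtered = None
        for q in quantiles:
            cfg_q = replace(config, cut_quantile=q)
            init = initial_labels(tree, sub_tom, cfg_q)
            candidate = enforce_min_kme(sub_table, init, config)
            if candidate.module_names:
                filtered = candidate
                break
        if filtered is None:
            break
        for module in filtered.module_names:
            members = filtered.members(module)
            combined[members] = f"r{round_no}_{module}"
        remaining = [f for f in remaining if combined[f] == GREY]
    labels = enforce_min_kme(table, ModuleAssignment(combined), config)
    if config.merge_modules and len(labels.module_names) >= 2:
        labels = merge_close_modules(table, labels, config)
        labels = enforce_min_kme(table, labels, config)
    return assign_colors(labels)
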